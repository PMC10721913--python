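"""End-to-end orchestration: simulate, preprocess, reject, decode, infer, report.

A run is driven by a single YAML/JSON config and a master seed.  Every
stage writes its artifacts under the run directory and can be re-run
from the previous stage's outputs; per-stage and per-subject seeds are
derived deterministically from the master seed (SHA-256 of the tag
path, reduced mod 2^31), so partial re-runs reproduce full-run values.
A manifest records the config hash, derived seeds, stage timings and a
checksum inventory of every output file: identical config + seed gives
identical checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .artifacts import two_step_rejection
from .data_model import ConditionPair, EpochedDataset, read_container, write_container
from .decoding import (
    cross_classify_timecourse,
    decode_timecourse,
    temporal_generalization,
)
from .group_stats import (
    TFCEParams,
    ZMap,
    build_permutation_null,
    extract_clusters,
    group_tfce,
    paired_accuracy_difference,
    repeat_and_average_zmaps,
    z_from_null,
)
from .preprocessing import PreprocessingConfig, preprocess
from .synthetic import ArtifactSpec, EffectSpec, SimulationConfig, generate_study

logger = logging.getLogger(__name__)


def derive_seed(master: int, *tags) -> int:
    """Deterministic sub-seed from the master seed and a tag path."""
    key = ":".join([str(int(master))] + [str(t) for t in tags])
    digest = hashlib.sha256(key.encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


# ---------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------

@dataclass
class RunConfig:
    """Validated pipeline configuration (see ``from_dict`` for the schema)."""

    seed: int
    simulation: SimulationConfig
    preprocessing: PreprocessingConfig | None
    analysis_window: tuple[float, float]
    rejection: bool
    pairs: list[ConditionPair]
    cross: list[tuple[ConditionPair, str]]
    tg: list[tuple[ConditionPair, str]]
    paired: list[tuple[ConditionPair, ConditionPair]]
    k: int = 10
    n_repetitions: int = 20
    shrinkage: float | str = "ledoit-wolf"
    n_perm: int = 100
    z_crit: float = 1.96
    tfce: TFCEParams = field(default_factory=TFCEParams)

    @staticmethod
    def from_dict(d: dict) -> "RunConfig":
        if "seed" not in d:
            raise ValueError("config must declare a master seed")
        sim = d.get("simulation", {})
        effects = tuple(
            EffectSpec(
                conditions=tuple(e["conditions"]),
                window=tuple(e["window"]),
                amplitude=float(e["amplitude"]),
                envelope=e.get("envelope", "boxcar"),
                topography=e.get("topography", i),
            )
            for i, e in enumerate(sim.pop("effects", []))
        )
        art = sim.pop("artifact_spec", None)
        sim_cfg = SimulationConfig(
            effects=effects,
            artifact_spec=None if art is None else ArtifactSpec(**art),
            seed=derive_seed(d["seed"], "simulate"),
            **{k: tuple(v) if isinstance(v, list) else v for k, v in sim.items()},
        )
        prep = d.get("preprocessing", {"enabled": True})
        enabled = prep.pop("enabled", True) if isinstance(prep, dict) else True
        prep_cfg = (
            PreprocessingConfig(
                **{k: tuple(v) if isinstance(v, list) else v for k, v in prep.items()}
            )
            if enabled
            else None
        )
        dec = d.get("decoding", {})
        conditions = set(sim_cfg.conditions)

        def _pair(p) -> ConditionPair:
            pair = ConditionPair(*p)
            unknown = {pair.target, pair.control} - conditions
            if unknown:
                raise ValueError(f"pair references unknown condition(s) {unknown}")
            return pair

        pairs = [_pair(p) for p in dec.get("pairs", [])]
        cross = []
        for c in dec.get("cross", []):
            pair, test = _pair(c["train"]), c["test"]
            if test not in conditions:
                raise ValueError(f"cross test condition {test!r} unknown")
            cross.append((pair, test))
        tg = []
        for c in dec.get("tg", []):
            pair, test = _pair(c["train"]), c["test"]
            if test not in conditions:
                raise ValueError(f"tg test condition {test!r} unknown")
            tg.append((pair, test))
        paired = [
            (_pair(a), _pair(b)) for a, b in d.get("stats", {}).get("paired", [])
        ]
        stats = d.get("stats", {})
        tfce_d = stats.get("tfce", {})
        return RunConfig(
            seed=int(d["seed"]),
            simulation=sim_cfg,
            preprocessing=prep_cfg,
            analysis_window=tuple(d.get("analysis_window", (-100.0, 500.0))),
            rejection=bool(d.get("rejection", {}).get("enabled", True))
            if isinstance(d.get("rejection", True), dict)
            else bool(d.get("rejection", True)),
            pairs=pairs,
            cross=cross,
            tg=tg,
            paired=paired,
            k=int(dec.get("k", 10)),
            n_repetitions=int(dec.get("n_repetitions", 20)),
            shrinkage=dec.get("shrinkage", "ledoit-wolf"),
            n_perm=int(stats.get("n_perm", 100)),
            z_crit=float(stats.get("z_crit", 1.96)),
            tfce=TFCEParams(
                E=float(tfce_d.get("E", 0.5)),
                H=float(tfce_d.get("H", 2.0)),
                dh=tfce_d.get("dh"),
                n_steps=int(tfce_d.get("n_steps", 100)),
            ),
        )

    @staticmethod
    def from_file(path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        d = yaml.safe_load(text)
        return RunConfig.from_dict(d)


def pair_name(pair: ConditionPair) -> str:
    return f"{pair.target}_vs_{pair.control}"


# ---------------------------------------------------------------------
# group-level analyses wiring decoding into the permutation machinery
# ---------------------------------------------------------------------

def group_decoding_zmap(
    datasets: list[EpochedDataset],
    pair: ConditionPair,
    k: int = 10,
    n_repetitions: int = 20,
    n_perm: int = 100,
    shrinkage: float | str = "ledoit-wolf",
    seed: int = 0,
    tfce: TFCEParams = TFCEParams(),
    z_crit: float = 1.96,
    null_scope: str = "per-repetition",
) -> ZMap:
    """Repetition-averaged TFCE-permutation z-map for one condition pair.

    Each repetition is a complete analysis: per-subject accuracy maps
    with that repetition's fold assignment, a label-permutation null of
    ``n_perm`` maximal statistics, and the rank-based z conversion; the
    ``n_repetitions`` z-maps are averaged.  With
    ``null_scope="per-repetition"`` (default) the null is redrawn for
    every repetition; ``"shared"`` draws it once and reuses it across
    repetitions — the same null distribution at a fraction of the cost,
    appropriate for large Monte-Carlo validation runs.
    """
    times = datasets[0].times

    def one_subject(ds: EpochedDataset, rep, rng=None) -> np.ndarray:
        return decode_timecourse(
            ds, pair, k=k, n_repetitions=1, shrinkage=shrinkage,
            seed=derive_seed(seed, "folds", rep, ds.subject_id),
            permute_labels_rng=rng,
        ).accuracies[0]

    shared_null = None
    if null_scope == "shared":
        shared_null = build_permutation_null(
            lambda rng: np.stack([one_subject(ds, "null", rng) for ds in datasets]),
            n_perm=n_perm,
            seed=derive_seed(seed, "null"),
            baseline=0.5,
            params=tfce,
        )
    elif null_scope != "per-repetition":
        raise ValueError("null_scope must be 'per-repetition' or 'shared'")

    def analysis(rep: int) -> ZMap:
        obs = np.stack([one_subject(ds, rep) for ds in datasets])
        observed = group_tfce(obs, 0.5, tfce)
        if shared_null is not None:
            null_max, null_min = shared_null
        else:
            null_max, null_min = build_permutation_null(
                lambda rng: np.stack(
                    [one_subject(ds, rep, rng) for ds in datasets]
                ),
                n_perm=n_perm,
                seed=derive_seed(seed, "null", rep),
                baseline=0.5,
                params=tfce,
            )
        return z_from_null(
            observed, null_max, null_min, times=times,
            accuracy=obs.mean(axis=0), z_crit=z_crit,
        )

    return repeat_and_average_zmaps(analysis, n_repetitions, z_crit=z_crit)


def group_cross_zmap(
    datasets: list[EpochedDataset],
    train_pair: ConditionPair,
    test_condition: str,
    n_repetitions: int = 20,
    n_perm: int = 100,
    shrinkage: float | str = "ledoit-wolf",
    seed: int = 0,
    tfce: TFCEParams = TFCEParams(),
    z_crit: float = 1.96,
    null_scope: str = "per-repetition",
) -> ZMap:
    """Repetition-averaged z-map for a cross-classification score map.

    The permutation null shuffles the training-pair labels within each
    subject and recomputes the cross-classification scores.
    ``null_scope`` as in :func:`group_decoding_zmap`.
    """
    times = datasets[0].times

    def one_subject(ds: EpochedDataset, rep, rng=None) -> np.ndarray:
        return cross_classify_timecourse(
            ds, train_pair, test_condition, n_repetitions=1, shrinkage=shrinkage,
            seed=derive_seed(seed, "balance", rep, ds.subject_id),
            permute_labels_rng=rng,
        ).accuracies[0]

    shared_null = None
    if null_scope == "shared":
        shared_null = build_permutation_null(
            lambda rng: np.stack([one_subject(ds, "null", rng) for ds in datasets]),
            n_perm=n_perm,
            seed=derive_seed(seed, "null"),
            baseline=0.5,
            params=tfce,
        )
    elif null_scope != "per-repetition":
        raise ValueError("null_scope must be 'per-repetition' or 'shared'")

    def analysis(rep: int) -> ZMap:
        obs = np.stack([one_subject(ds, rep) for ds in datasets])
        observed = group_tfce(obs, 0.5, tfce)
        if shared_null is not None:
            null_max, null_min = shared_null
        else:
            null_max, null_min = build_permutation_null(
                lambda rng: np.stack(
                    [one_subject(ds, rep, rng) for ds in datasets]
                ),
                n_perm=n_perm,
                seed=derive_seed(seed, "null", rep),
                baseline=0.5,
                params=tfce,
            )
        return z_from_null(
            observed, null_max, null_min, times=times,
            accuracy=obs.mean(axis=0), z_crit=z_crit,
        )

    return repeat_and_average_zmaps(analysis, n_repetitions, z_crit=z_crit)


# ---------------------------------------------------------------------
# pipeline stages
# ---------------------------------------------------------------------

def _subject_paths(stage_dir: Path) -> list[Path]:
    # container sidecars only (not *_groundtruth.json / *_rejection.json)
    return sorted(
        p for p in stage_dir.glob("sub-*.json")
        if (p.with_suffix(".npy")).exists() and "_" not in p.stem[4:]
    )


def _latest_stage_dir(run_dir: Path) -> Path:
    for name in ("rejected", "preprocessed", "simulated"):
        d = run_dir / name
        if d.exists() and _subject_paths(d):
            return d
    raise FileNotFoundError(f"no subject containers under {run_dir}")


def stage_simulate(cfg: RunConfig, run_dir: Path) -> None:
    out = run_dir / "simulated"
    out.mkdir(parents=True, exist_ok=True)
    for ds, gt in generate_study(cfg.simulation):
        write_container(ds, out / ds.subject_id)
        gt_path = out / f"{ds.subject_id}_groundtruth.json"
        gt_path.write_text(
            json.dumps(
                {
                    "effect_windows": [list(w) for w in gt.effect_windows],
                    "effect_conditions": [list(c) for c in gt.effect_conditions],
                    "effect_amplitudes": gt.effect_amplitudes,
                    "artifact_trials": gt.artifact_trials.tolist(),
                    "artifact_pairs": gt.artifact_pairs,
                },
                indent=1,
            )
        )
    logger.info("simulate: %d subjects -> %s", cfg.simulation.n_subjects, out)


def stage_preprocess(cfg: RunConfig, run_dir: Path) -> None:
    if cfg.preprocessing is None:
        logger.info("preprocess: disabled")
        return
    out = run_dir / "preprocessed"
    out.mkdir(parents=True, exist_ok=True)
    for path in _subject_paths(run_dir / "simulated"):
        ds = read_container(path)
        write_container(preprocess(ds, cfg.preprocessing), out / ds.subject_id)
    logger.info("preprocess: -> %s", out)


def stage_reject(cfg: RunConfig, run_dir: Path) -> None:
    if not cfg.rejection:
        logger.info("reject: disabled")
        return
    src = run_dir / ("preprocessed" if cfg.preprocessing else "simulated")
    out = run_dir / "rejected"
    out.mkdir(parents=True, exist_ok=True)
    summaries = []
    for path in _subject_paths(src):
        ds = read_container(path)
        clean, report = two_step_rejection(ds)
        write_container(clean, out / ds.subject_id)
        summaries.append({"subject": ds.subject_id, **report.summary()})
        (out / f"{ds.subject_id}_rejection.json").write_text(
            json.dumps(
                {
                    "electrode_thresholds": report.electrode_thresholds,
                    "excluded_trials": report.excluded_trials,
                    "interpolated": report.interpolated,
                    **report.summary(),
                },
                indent=1,
            )
        )
    pd.DataFrame(summaries).to_csv(out / "rejection_summary.csv", index=False)
    logger.info("reject: -> %s", out)


def _load_analysis_datasets(cfg: RunConfig, run_dir: Path) -> list[EpochedDataset]:
    from .preprocessing import crop_epoch

    datasets = []
    for path in _subject_paths(_latest_stage_dir(run_dir)):
        ds = read_container(path)
        if cfg.analysis_window is not None:
            ds = crop_epoch(ds, cfg.analysis_window)
        datasets.append(ds)
    return datasets


def stage_decode(cfg: RunConfig, run_dir: Path) -> None:
    out = run_dir / "decoding"
    out.mkdir(parents=True, exist_ok=True)
    datasets = _load_analysis_datasets(cfg, run_dir)
    times = datasets[0].times
    for pair in cfg.pairs:
        name = pair_name(pair)
        acc = np.stack(
            [
                decode_timecourse(
                    ds, pair, k=cfg.k, n_repetitions=cfg.n_repetitions,
                    shrinkage=cfg.shrinkage,
                    seed=derive_seed(cfg.seed, "decode", name, ds.subject_id),
                ).accuracies
                for ds in datasets
            ]
        )  # (n_subjects, n_repetitions, n_times)
        np.save(out / f"acc_{name}.npy", acc)
        pd.DataFrame(
            {"time_ms": times, "mean_accuracy": acc.mean(axis=(0, 1))}
        ).to_csv(out / f"acc_{name}.csv", index=False)
    for pair, test in cfg.cross:
        name = f"train_{pair_name(pair)}_test_{test}"
        acc = np.stack(
            [
                cross_classify_timecourse(
                    ds, pair, test, n_repetitions=cfg.n_repetitions,
                    shrinkage=cfg.shrinkage,
                    seed=derive_seed(cfg.seed, "cross", name, ds.subject_id),
                ).accuracies
                for ds in datasets
            ]
        )
        np.save(out / f"cross_{name}.npy", acc)
        pd.DataFrame(
            {"time_ms": times, "mean_score": acc.mean(axis=(0, 1))}
        ).to_csv(out / f"cross_{name}.csv", index=False)
    for pair, test in cfg.tg:
        name = f"train_{pair_name(pair)}_test_{test}"
        tg = np.stack(
            [
                temporal_generalization(
                    ds, pair, test, n_repetitions=cfg.n_repetitions,
                    shrinkage=cfg.shrinkage,
                    seed=derive_seed(cfg.seed, "cross", name, ds.subject_id),
                ).values
                for ds in datasets
            ]
        )  # (n_subjects, n_repetitions, T, T)
        np.save(out / f"tg_{name}.npy", tg)
    np.save(out / "times.npy", times)
    logger.info("decode: -> %s", out)


def _save_zmap(zmap: ZMap, out: Path, name: str) -> None:
    df = pd.DataFrame(
        {
            "time_ms": zmap.times,
            "z": zmap.z,
            "accuracy": np.full_like(zmap.z, np.nan)
            if zmap.accuracy is None
            else zmap.accuracy,
            "significant": zmap.mask.astype(int),
        }
    )
    df.to_csv(out / f"zmap_{name}.csv", index=False)
    clusters = [
        {
            "onset_ms": c.onset,
            "offset_ms": c.offset,
            "peak_time_ms": c.peak_time,
            "peak_z": c.peak_z,
            "peak_accuracy": c.peak_accuracy,
            "sign": c.sign,
        }
        for c in zmap.clusters
    ]
    (out / f"clusters_{name}.json").write_text(json.dumps(clusters, indent=1))


def stage_stats(cfg: RunConfig, run_dir: Path) -> None:
    out = run_dir / "stats"
    out.mkdir(parents=True, exist_ok=True)
    datasets = _load_analysis_datasets(cfg, run_dir)
    for pair in cfg.pairs:
        name = pair_name(pair)
        zmap = group_decoding_zmap(
            datasets, pair, k=cfg.k, n_repetitions=cfg.n_repetitions,
            n_perm=cfg.n_perm, shrinkage=cfg.shrinkage,
            seed=derive_seed(cfg.seed, "stats", name),
            tfce=cfg.tfce, z_crit=cfg.z_crit,
        )
        _save_zmap(zmap, out, name)
    for pair, test in cfg.cross:
        name = f"train_{pair_name(pair)}_test_{test}"
        zmap = group_cross_zmap(
            datasets, pair, test, n_repetitions=cfg.n_repetitions,
            n_perm=cfg.n_perm, shrinkage=cfg.shrinkage,
            seed=derive_seed(cfg.seed, "stats", name),
            tfce=cfg.tfce, z_crit=cfg.z_crit,
        )
        _save_zmap(zmap, out, name)
    for pair_a, pair_b in cfg.paired:
        name = f"{pair_name(pair_a)}_minus_{pair_name(pair_b)}"
        acc_a = np.load(run_dir / "decoding" / f"acc_{pair_name(pair_a)}.npy")
        acc_b = np.load(run_dir / "decoding" / f"acc_{pair_name(pair_b)}.npy")
        times = np.load(run_dir / "decoding" / "times.npy")

        def analysis(rep: int, _a=acc_a, _b=acc_b, _t=times, _n=name) -> ZMap:
            return paired_accuracy_difference(
                _a[:, rep], _b[:, rep], _t, n_perm=cfg.n_perm,
                seed=derive_seed(cfg.seed, "paired", _n, rep),
                params=cfg.tfce, z_crit=cfg.z_crit,
            )

        zmap = repeat_and_average_zmaps(
            analysis, min(cfg.n_repetitions, acc_a.shape[1]), z_crit=cfg.z_crit
        )
        _save_zmap(zmap, out, name)
    logger.info("stats: -> %s", out)


def report_tables(run_dir: str | Path) -> list[Path]:
    """Regenerate cluster tables from serialized z-maps (idempotent).

    One table per comparison: onset, offset, peak time, peak z, peak
    accuracy per cluster, in the layout used for peak-latency
    reporting; plus an onset-latency summary across comparisons.
    """
    run_dir = Path(run_dir)
    stats_dir = run_dir / "stats"
    zmaps = sorted(stats_dir.glob("zmap_*.csv"))
    if not zmaps:
        raise FileNotFoundError(f"no z-map artifacts under {stats_dir}")
    out_paths = []
    onsets = []
    for path in zmaps:
        name = path.stem[len("zmap_"):]
        df = pd.read_csv(path)
        z_crit = 1.96
        clusters = extract_clusters(
            df["z"].to_numpy(), df["time_ms"].to_numpy(), z_crit,
            accuracy=df["accuracy"].to_numpy(),
        )
        rows = [
            {
                "comparison": name,
                "cluster": i + 1,
                "onset_ms": c.onset,
                "offset_ms": c.offset,
                "peak_time_ms": c.peak_time,
                "peak_z": round(c.peak_z, 2),
                "peak_accuracy": None
                if c.peak_accuracy is None
                else round(c.peak_accuracy, 2),
                "sign": c.sign,
            }
            for i, c in enumerate(clusters)
        ]
        table = pd.DataFrame(
            rows,
            columns=[
                "comparison", "cluster", "onset_ms", "offset_ms",
                "peak_time_ms", "peak_z", "peak_accuracy", "sign",
            ],
        )
        table_path = run_dir / "tables" / f"table_{name}.csv"
        table_path.parent.mkdir(parents=True, exist_ok=True)
        table.to_csv(table_path, index=False)
        out_paths.append(table_path)
        if clusters:
            onsets.append({"comparison": name, "onset_ms": clusters[0].onset})
        else:
            onsets.append({"comparison": name, "onset_ms": None})
    onset_path = run_dir / "tables" / "onset_summary.csv"
    pd.DataFrame(onsets).to_csv(onset_path, index=False)
    out_paths.append(onset_path)
    return out_paths


# ---------------------------------------------------------------------
# full run
# ---------------------------------------------------------------------

STAGES = ("simulate", "preprocess", "reject", "decode", "stats", "report")


def run_pipeline(config_path: str | Path, output_dir: str | Path) -> dict:
    """Run every stage in order; return (and write) the run manifest."""
    cfg = RunConfig.from_file(config_path)
    run_dir = Path(output_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    config_text = Path(config_path).read_text()
    timings: dict[str, float] = {}
    for stage in STAGES:
        t0 = time.perf_counter()
        try:
            if stage == "simulate":
                stage_simulate(cfg, run_dir)
            elif stage == "preprocess":
                stage_preprocess(cfg, run_dir)
            elif stage == "reject":
                stage_reject(cfg, run_dir)
            elif stage == "decode":
                stage_decode(cfg, run_dir)
            elif stage == "stats":
                stage_stats(cfg, run_dir)
            else:
                report_tables(run_dir)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
        timings[stage] = round(time.perf_counter() - t0, 3)
    inventory = {
        str(p.relative_to(run_dir)): _sha256(p)
        for p in sorted(run_dir.rglob("*"))
        if p.is_file() and p.name != "manifest.json"
    }
    manifest = {
        "config_sha256": hashlib.sha256(config_text.encode()).hexdigest(),
        "version": __version__,
        "master_seed": cfg.seed,
        "stage_seeds": {s: derive_seed(cfg.seed, s) for s in STAGES},
        "timings_s": timings,
        "files": inventory,
    }
    (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
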