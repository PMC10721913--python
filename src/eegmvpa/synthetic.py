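"""Synthetic epoched EEG with known category structure.

The generator emulates a visual-categorization EEG study: four
conditions (hands, tools, feet, animals), 128 trials each, 63 scalp
channels plus two mastoids, 1000 Hz sampling, epochs from -500 to
500 ms.  Category-selective responses are injected as rank-one
spatiotemporal patterns — a unit-norm channel topography times a
temporal envelope times an amplitude in microvolts — added to the
trials of the conditions that carry the effect.  A pattern shared by
two conditions (e.g. hands and tools) but absent from a third is the
synthetic analogue of a neural code that cross-classifies between
categories.

Noise is AR(1) over time by default (EEG-like temporal autocorrelation,
coefficient rho, unit marginal SD scaled to ``noise_sd``); white noise
is available for analytic checks.  Artifact trials are implanted by
scaling selected trial x electrode segments so their peak-to-peak
amplitude exceeds the clean range by a configurable multiplier, which
is exactly the quantity the downstream rejection stage thresholds.

Everything is reproducible from ``(cfg.seed, subject_index)``, and every
generated dataset comes with a :class:`GroundTruth` record of what was
implanted where.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from .data_model import ChannelInfo, EpochedDataset

DEFAULT_CONDITIONS = ("hands", "tools", "feet", "animals")

ENVELOPES = ("boxcar", "half-cosine")


def make_topography(seed: int, n_channels: int) -> np.ndarray:
    """Deterministic unit-norm channel-weight vector for an effect."""
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    rng = np.random.default_rng(seed)
    v = rng.standard_normal(n_channels)
    return v / np.linalg.norm(v)


def scalp_positions(n_scalp: int) -> np.ndarray:
    """Quasi-uniform unit-sphere positions on the upper hemisphere.

    A Fibonacci lattice restricted to z >= 0 — a stand-in electrode
    montage with realistic pairwise-distance structure for
    interpolation; no attempt at 10-20 naming fidelity.
    """
    i = np.arange(n_scalp)
    z = (i + 0.5) / n_scalp          # heights in (0, 1): upper hemisphere
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(1.0 - z**2)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def default_channels(n_scalp: int) -> list[ChannelInfo]:
    pos = scalp_positions(n_scalp)
    channels = [
        ChannelInfo(f"E{i + 1:02d}", "scalp", tuple(pos[i])) for i in range(n_scalp)
    ]
    channels.append(ChannelInfo("M1", "mastoid", (-0.95, -0.25, -0.2)))
    channels.append(ChannelInfo("M2", "mastoid", (0.95, -0.25, -0.2)))
    return channels


@dataclass(frozen=True)
class EffectSpec:
    """A rank-one condition-selective pattern.

    ``conditions`` carry the pattern; ``window`` is [t_start, t_end) in
    ms; ``amplitude`` is the peak strength in microvolts; ``topography``
    is either an integer seed for :func:`make_topography` or an explicit
    weight vector (normalized to unit Euclidean norm over scalp
    channels).
    """

    conditions: tuple[str, ...]
    window: tuple[float, float]
    amplitude: float
    envelope: str = "boxcar"
    topography: int | tuple[float, ...] = 0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.envelope not in ENVELOPES:
            raise ValueError(f"envelope must be one of {ENVELOPES}")
        if not self.window[0] < self.window[1]:
            raise ValueError("window must satisfy t_start < t_end")

    def envelope_values(self, times: np.ndarray) -> np.ndarray:
        """Envelope sampled at ``times`` (ms); zero outside the window."""
        t0, t1 = self.window
        inside = (times >= t0) & (times < t1)
        env = np.zeros_like(times, dtype=float)
        if self.envelope == "boxcar":
            env[inside] = 1.0
        else:  # half-cosine arch: 0 at the edges, 1 at the centre
            env[inside] = np.sin(np.pi * (times[inside] - t0) / (t1 - t0))
        return env

    def topography_vector(self, n_scalp: int) -> np.ndarray:
        if isinstance(self.topography, (int, np.integer)):
            return make_topography(int(self.topography), n_scalp)
        v = np.asarray(self.topography, dtype=float)
        if v.shape != (n_scalp,):
            raise ValueError(
                f"explicit topography has length {v.size}, expected {n_scalp}"
            )
        return v / np.linalg.norm(v)


@dataclass(frozen=True)
class ArtifactSpec:
    """Which fraction of trials/electrodes to corrupt, and how hard."""

    trial_fraction: float = 0.05
    electrode_fraction: float = 0.016   # ~1 of 63 electrodes
    p2p_multiplier: float = 10.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.trial_fraction <= 1.0:
            raise ValueError("trial_fraction must be in [0, 1]")
        if not 0.0 <= self.electrode_fraction <= 1.0:
            raise ValueError("electrode_fraction must be in [0, 1]")


@dataclass
class SimulationConfig:
    """Study-level generator settings.

    Defaults mirror the emulated study design: 14 subjects, four
    conditions with 128 trials each (512 per subject), 63 scalp
    channels + 2 mastoids, 1000 Hz sampling, epochs [-500, 500) ms.
    """

    n_subjects: int = 14
    n_trials_per_condition: int = 128
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    n_scalp_channels: int = 63
    sfreq: float = 1000.0
    epoch_window: tuple[float, float] = (-500.0, 500.0)
    noise_sd: float = 1.0
    noise_model: str = "ar1"      # "ar1" | "white"
    ar_coef: float = 0.5
    spatial_corr: float = 0.3     # uniform pairwise channel correlation
    effects: tuple[EffectSpec, ...] = ()
    artifact_spec: ArtifactSpec | None = None
    amplitude_jitter_frac: float = 0.2   # between-subject SD as fraction of amplitude
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_model not in ("ar1", "white"):
            raise ValueError("noise_model must be 'ar1' or 'white'")
        self.effects = tuple(self.effects)
        t0, t1 = self.epoch_window
        for eff in self.effects:
            if eff.window[0] < t0 or eff.window[1] > t1:
                raise ValueError(
                    f"effect window {eff.window} outside epoch {self.epoch_window}"
                )
            unknown = set(eff.conditions) - set(self.conditions)
            if unknown:
                raise ValueError(f"effect references unknown conditions {unknown}")

    @property
    def times(self) -> np.ndarray:
        dt = 1000.0 / self.sfreq
        n = int(round((self.epoch_window[1] - self.epoch_window[0]) / dt))
        return self.epoch_window[0] + dt * np.arange(n)


@dataclass
class GroundTruth:
    """What was implanted: effect structure and artifact locations."""

    effect_windows: list[tuple[float, float]] = field(default_factory=list)
    effect_conditions: list[tuple[str, ...]] = field(default_factory=list)
    effect_topographies: list[np.ndarray] = field(default_factory=list)
    effect_amplitudes: list[float] = field(default_factory=list)
    artifact_trials: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    artifact_pairs: list[tuple[int, int]] = field(default_factory=list)


def _noise(rng: np.random.Generator, shape, cfg: SimulationConfig) -> np.ndarray:
    """Noise with marginal SD = cfg.noise_sd; AR(1) runs along time.

    ``spatial_corr`` mixes in a per-trial common field shared across
    channels, giving EEG-like uniform pairwise channel correlation (so
    channel interpolation behaves realistically); temporal structure is
    applied afterward, preserving the marginal SD.
    """
    if cfg.noise_model == "white" or cfg.ar_coef == 0.0:
        return _spatial_mix(rng.standard_normal(shape), rng, cfg) * cfg.noise_sd
    rho = cfg.ar_coef
    # innovations scaled so the stationary marginal variance is noise_sd^2;
    # the first sample is drawn from the stationary distribution directly,
    # then y_t = e_t + rho*y_{t-1} is run as an IIR filter.
    innov = _spatial_mix(rng.standard_normal(shape), rng, cfg)
    innov *= cfg.noise_sd * np.sqrt(1.0 - rho**2)
    innov[..., 0] = (
        _spatial_mix(rng.standard_normal(shape[:-1] + (1,)), rng, cfg)[..., 0]
        * cfg.noise_sd
    )
    return lfilter([1.0], [1.0, -rho], innov, axis=-1)


def _spatial_mix(
    eps: np.ndarray, rng: np.random.Generator, cfg: SimulationConfig
) -> np.ndarray:
    """Blend unit-variance channel noise with a shared common field.

    Input/output shape (..., n_channels, n_times); pairwise channel
    correlation is ``cfg.spatial_corr``; marginal variance stays 1.
    """
    c = cfg.spatial_corr
    if c <= 0:
        return eps
    common = rng.standard_normal(eps.shape[:-2] + (1,) + eps.shape[-1:])
    return np.sqrt(1.0 - c) * eps + np.sqrt(c) * common


def generate_subject(
    cfg: SimulationConfig, subject_index: int
) -> tuple[EpochedDataset, GroundTruth]:
    """One subject's epoched data plus its ground truth.

    Trials are i.i.d. given condition: signal = sum of effect patterns
    carried by the trial's condition, plus noise.  Mastoid channels are
    pure noise (no effect loading).  Fully reproducible from
    ``(cfg.seed, subject_index)``.
    """
    rng = np.random.default_rng([cfg.seed, subject_index])
    times = cfg.times
    n_cond = len(cfg.conditions)
    n_trials = n_cond * cfg.n_trials_per_condition
    n_scalp = cfg.n_scalp_channels
    n_channels = n_scalp + 2
    channels = default_channels(n_scalp)

    labels = np.repeat(list(cfg.conditions), cfg.n_trials_per_condition)
    order = rng.permutation(n_trials)   # interleave conditions
    labels = labels[order]

    data = _noise(rng, (n_trials, n_channels, len(times)), cfg)

    gt = GroundTruth()
    for eff in cfg.effects:
        amp = eff.amplitude
        if cfg.amplitude_jitter_frac > 0:
            amp = max(
                0.0, amp * (1.0 + cfg.amplitude_jitter_frac * rng.standard_normal())
            )
        topo = eff.topography_vector(n_scalp)
        env = eff.envelope_values(times)
        pattern = amp * topo[:, None] * env[None, :]    # (n_scalp, n_times)
        carrier = np.isin(labels, eff.conditions)
        data[np.ix_(carrier, np.arange(n_scalp))] += pattern[None]
        gt.effect_windows.append(eff.window)
        gt.effect_conditions.append(eff.conditions)
        gt.effect_topographies.append(topo)
        gt.effect_amplitudes.append(amp)

    if cfg.artifact_spec is not None and cfg.artifact_spec.trial_fraction > 0:
        spec = cfg.artifact_spec
        n_art_trials = int(np.floor(spec.trial_fraction * n_trials))
        n_art_el = max(1, int(round(spec.electrode_fraction * n_scalp)))
        art_trials = rng.choice(n_trials, size=n_art_trials, replace=False)
        art_trials.sort()
        # clean p2p reference: 99th percentile over scalp trial x channel
        p2p = np.ptp(data[:, :n_scalp, :], axis=-1)
        target = spec.p2p_multiplier * np.percentile(p2p, 99)
        for tr in art_trials:
            bad_els = rng.choice(n_scalp, size=n_art_el, replace=False)
            for el in bad_els:
                seg = data[tr, el]
                center = seg.mean()
                cur = np.ptp(seg)
                data[tr, el] = center + (seg - center) * (target / cur)
                gt.artifact_pairs.append((int(tr), int(el)))
        gt.artifact_trials = art_trials

    ds = EpochedDataset(
        data=data,
        times=times,
        sfreq=cfg.sfreq,
        labels=labels,
        channels=channels,
        subject_id=f"sub-{subject_index + 1:02d}",
        conditions=cfg.conditions,
    )
    return ds, gt


def generate_study(cfg: SimulationConfig) -> list[tuple[EpochedDataset, GroundTruth]]:
    """Independent noise per subject, shared effect structure."""
    return [generate_subject(cfg, i) for i in range(cfg.n_subjects)]
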