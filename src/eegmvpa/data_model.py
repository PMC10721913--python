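"""Core data containers shared by all pipeline stages.

The lingua franca of the pipeline is :class:`EpochedDataset`: a
trials x channels x time tensor of epoched EEG (microvolts), with a
millisecond time axis locked to stimulus onset, per-trial condition
labels, and explicit channel metadata.  Channel roles (scalp / mastoid /
EOG) are declared per channel rather than inferred from name patterns,
so that re-referencing, artifact rejection and decoding operate on a
deterministic channel set.

Datasets are stored on disk as a ``.npy`` array plus a JSON metadata
sidecar — a deliberately simple, inspectable container.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

SCHEMA = "epoched-eeg/1"

CHANNEL_ROLES = ("scalp", "mastoid", "eog")


class ValidationError(ValueError):
    """An EpochedDataset (or container file) violates its invariants."""


@dataclass(frozen=True)
class ChannelInfo:
    """A single channel: unique name, role, and 3-D head-model position.

    Positions live on (approximately) a unit sphere in arbitrary
    head-model units; they are only used for distance-weighted
    interpolation, so the absolute scale is irrelevant.
    """

    name: str
    role: str = "scalp"
    position: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def __post_init__(self) -> None:
        if self.role not in CHANNEL_ROLES:
            raise ValidationError(
                f"channel {self.name!r}: role {self.role!r} not in {CHANNEL_ROLES}"
            )
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValidationError(
                f"channel {self.name!r}: position must be 3 finite coordinates"
            )


@dataclass(frozen=True)
class ConditionPair:
    """A binary decoding contrast: target vs. control condition."""

    target: str
    control: str

    def __post_init__(self) -> None:
        if self.target == self.control:
            raise ValidationError("target and control conditions must differ")

    def __iter__(self):
        return iter((self.target, self.control))


@dataclass
class EpochedDataset:
    """Epoched multichannel EEG with labels and channel metadata.

    Parameters
    ----------
    data
        Array of shape (n_trials, n_channels, n_times), in microvolts.
    times
        Timepoints in ms relative to stimulus onset; strictly increasing
        with spacing 1000/sfreq.
    sfreq
        Sampling rate in Hz.
    labels
        Per-trial condition id, each a member of ``conditions``.
    channels
        Ordered channel metadata; names unique.
    conditions
        The declared condition set.  Defaults to the distinct labels.
    bad_mask
        Optional (n_trials, n_channels) boolean mask marking entries
        that were repaired by interpolation.
    """

    data: np.ndarray
    times: np.ndarray
    sfreq: float
    labels: np.ndarray
    channels: list[ChannelInfo]
    subject_id: str = ""
    conditions: tuple[str, ...] = ()
    bad_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.times = np.asarray(self.times, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=str)
        if not self.conditions:
            self.conditions = tuple(dict.fromkeys(self.labels.tolist()))
        self.validate()

    # -- invariants ---------------------------------------------------
    def validate(self) -> None:
        if self.data.ndim != 3:
            raise ValidationError(
                f"data must be 3-D (trials, channels, times), got {self.data.shape}"
            )
        n_trials, n_channels, n_times = self.data.shape
        if len(self.times) != n_times:
            raise ValidationError(
                f"times has length {len(self.times)}, data has {n_times} samples"
            )
        if n_times > 1:
            dt = np.diff(self.times)
            expected = 1000.0 / self.sfreq
            if np.any(dt <= 0) or np.any(np.abs(dt - expected) > 1e-9):
                raise ValidationError(
                    "times must be strictly increasing with spacing "
                    f"1000/sfreq = {expected:g} ms"
                )
        if len(self.labels) != n_trials:
            raise ValidationError(
                f"labels has length {len(self.labels)}, data has {n_trials} trials"
            )
        unknown = set(self.labels.tolist()) - set(self.conditions)
        if unknown:
            raise ValidationError(f"labels outside declared condition set: {unknown}")
        if len(self.channels) != n_channels:
            raise ValidationError(
                f"{len(self.channels)} ChannelInfo entries for {n_channels} channels"
            )
        names = [c.name for c in self.channels]
        if len(set(names)) != len(names):
            raise ValidationError("channel names must be unique")
        if self.bad_mask is not None:
            self.bad_mask = np.asarray(self.bad_mask, dtype=bool)
            if self.bad_mask.shape != (n_trials, n_channels):
                raise ValidationError(
                    f"bad_mask shape {self.bad_mask.shape} != "
                    f"{(n_trials, n_channels)}"
                )

    # -- convenience --------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    @property
    def channel_names(self) -> list[str]:
        return [c.name for c in self.channels]

    def channel_indices(self, role: str) -> np.ndarray:
        """Indices of channels with the given role, in channel order."""
        return np.array(
            [i for i, c in enumerate(self.channels) if c.role == role], dtype=int
        )

    @property
    def scalp_indices(self) -> np.ndarray:
        return self.channel_indices("scalp")

    def condition_counts(self) -> dict[str, int]:
        return {c: int(np.sum(self.labels == c)) for c in self.conditions}

    def copy(self) -> "EpochedDataset":
        return replace(
            self,
            data=self.data.copy(),
            times=self.times.copy(),
            labels=self.labels.copy(),
            channels=list(self.channels),
            bad_mask=None if self.bad_mask is None else self.bad_mask.copy(),
        )


# ---------------------------------------------------------------------
# Container I/O: <base>.npy (float64 tensor) + <base>.json (metadata)
# ---------------------------------------------------------------------

def _paths(path: str | Path) -> tuple[Path, Path]:
    base = Path(path)
    if base.suffix in {".npy", ".json"}:
        base = base.with_suffix("")
    return base.with_suffix(".npy"), base.with_suffix(".json")


def write_container(ds: EpochedDataset, path: str | Path) -> None:
    """Write a dataset as ``<path>.npy`` + ``<path>.json``.

    Lossless for 64-bit floats: the data tensor is stored verbatim in
    NumPy binary format, everything else in the JSON sidecar.
    """
    ds.validate()
    npy_path, json_path = _paths(path)
    npy_path.parent.mkdir(parents=True, exist_ok=True)
    meta = {
        "schema": SCHEMA,
        "subject_id": ds.subject_id,
        "sfreq": float(ds.sfreq),
        "times": ds.times.tolist(),
        "labels": ds.labels.tolist(),
        "conditions": list(ds.conditions),
        "channels": [
            {"name": c.name, "role": c.role, "position": list(map(float, c.position))}
            for c in ds.channels
        ],
        "bad_mask": None if ds.bad_mask is None else ds.bad_mask.astype(int).tolist(),
    }
    np.save(npy_path, ds.data)
    json_path.write_text(json.dumps(meta, indent=1))


def read_container(path: str | Path) -> EpochedDataset:
    """Read a dataset written by :func:`write_container`."""
    npy_path, json_path = _paths(path)
    for p in (npy_path, json_path):
        if not p.exists():
            raise FileNotFoundError(f"container file missing: {p}")
    meta = json.loads(json_path.read_text())
    required = {"schema", "sfreq", "times", "labels", "conditions", "channels"}
    missing = required - set(meta)
    if missing or meta.get("schema") != SCHEMA:
        raise ValidationError(
            f"container schema mismatch: expected {SCHEMA} with keys {sorted(required)}, "
            f"found schema={meta.get('schema')!r}, missing={sorted(missing)}"
        )
    data = np.load(npy_path)
    channels = [
        ChannelInfo(c["name"], c["role"], tuple(c["position"]))
        for c in meta["channels"]
    ]
    bad_mask = meta.get("bad_mask")
    return EpochedDataset(
        data=data,
        times=np.asarray(meta["times"], dtype=float),
        sfreq=meta["sfreq"],
        labels=np.asarray(meta["labels"], dtype=str),
        channels=channels,
        subject_id=meta.get("subject_id", ""),
        conditions=tuple(meta["conditions"]),
        bad_mask=None if bad_mask is None else np.asarray(bad_mask, dtype=bool),
    )


def select_conditions(ds: EpochedDataset, conditions) -> EpochedDataset:
    """Return the trials of the requested conditions, order preserved.

    The input is never mutated; the channel set is unchanged.  The
    returned dataset declares only the selected conditions.
    """
    conditions = list(conditions)
    unknown = set(conditions) - set(ds.conditions)
    if unknown:
        raise KeyError(f"unknown condition(s): {sorted(unknown)}")
    keep = np.isin(ds.labels, conditions)
    return EpochedDataset(
        data=ds.data[keep].copy(),
        times=ds.times.copy(),
        sfreq=ds.sfreq,
        labels=ds.labels[keep].copy(),
        channels=list(ds.channels),
        subject_id=ds.subject_id,
        conditions=tuple(conditions),
        bad_mask=None if ds.bad_mask is None else ds.bad_mask[keep].copy(),
    )
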