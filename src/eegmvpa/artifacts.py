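"""Automatic peak-to-peak artifact rejection with a data-driven threshold.

Given a group of equal-length time signals (e.g. all trials of one
electrode), the rejection rule thresholds their peak-to-peak (p2p)
amplitudes.  The threshold is not fixed a priori: every observed p2p
value is a candidate, and the chosen threshold theta* minimizes

    J(theta) = sum_t ( mean_{p2p <= theta}(signal_t) - median_all(signal_t) )^2,

the squared distance between the mean of the under-threshold signals
and the pointwise median waveform of the whole group.  The median is
robust to the very outliers being hunted, so keeping an artifact drags
the mean away from it and raises J.  Ties are broken toward the largest
threshold (reject the least data).

The two-step procedure applies this rule (1) across trials for each
electrode, marking electrode-wise bad trials, then (2) across
electrodes for each trial, marking trial-wise bad electrodes.  After
each pass, a trial with fewer than half its scalp electrodes marked is
repaired by inverse-distance-weighted interpolation from the clean
electrodes; a trial with at least half marked is excluded.  Mastoid and
EOG channels are never auto-rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_model import EpochedDataset


def peak_to_peak(signal: np.ndarray) -> float:
    """max - min of a time signal; raises on NaN."""
    signal = np.asarray(signal, dtype=float)
    if signal.size == 0:
        raise ValueError("empty signal")
    if not np.all(np.isfinite(signal)):
        raise ValueError("signal contains NaN or infinite values")
    return float(np.max(signal) - np.min(signal))


def auto_threshold(signals: np.ndarray) -> tuple[float, np.ndarray]:
    """Data-driven p2p threshold over a group of signals.

    Parameters
    ----------
    signals
        Array (n_signals, n_times), n_signals >= 2.

    Returns
    -------
    threshold
        The p2p value theta* minimizing J (largest theta on ties).
    kept
        Sorted indices of signals with p2p <= theta*.
    """
    signals = np.asarray(signals, dtype=float)
    if signals.ndim != 2 or signals.shape[0] < 2:
        raise ValueError("need at least 2 equal-length signals")
    if not np.all(np.isfinite(signals)):
        raise ValueError("signals contain NaN or infinite values")

    p2p = np.ptp(signals, axis=1)
    order = np.argsort(p2p, kind="stable")
    sorted_p2p = p2p[order]
    median = np.median(signals, axis=0)

    # prefix means over signals sorted by p2p: mean of U(theta) for every
    # candidate is a prefix mean, so J over all candidates is O(n * T)
    prefix = np.cumsum(signals[order], axis=0)
    counts = np.arange(1, len(p2p) + 1, dtype=float)[:, None]
    J_all = np.sum((prefix / counts - median[None, :]) ** 2, axis=1)

    # candidates are the unique p2p values; each maps to the prefix that
    # includes every signal with that p2p (ties included)
    uniq_vals, counts_per = np.unique(sorted_p2p, return_counts=True)
    cum = np.cumsum(counts_per) - 1          # index of last signal per candidate
    J = J_all[cum]

    # tie-break toward the largest threshold; tolerance covers float
    # noise when signals (hence prefix means) coincide exactly
    tol = J.min() * 1e-9 + 1e-12 * (np.sum(median**2) + 1.0)
    best = np.flatnonzero(J <= J.min() + tol)[-1]
    threshold = float(uniq_vals[best])
    kept = np.sort(order[: cum[best] + 1])
    return threshold, kept


def interpolate_channels(
    trial_data: np.ndarray, bad_set, positions: np.ndarray
) -> np.ndarray:
    """Replace bad channels by an inverse-distance-weighted mean.

    ``trial_data`` is (n_channels, n_times); ``positions`` is
    (n_channels, 3).  Each bad channel becomes sum_g w_g * good_g with
    weights w_g proportional to 1/distance, normalized.  Good channels
    are untouched.
    """
    trial_data = np.asarray(trial_data, dtype=float)
    bad = sorted(set(int(b) for b in bad_set))
    n_ch = trial_data.shape[0]
    good = [i for i in range(n_ch) if i not in bad]
    if len(bad) >= n_ch / 2:
        raise ValueError("cannot interpolate half or more of the channels")
    if len(good) < 3:
        raise ValueError("need at least 3 good channels to interpolate")
    out = trial_data.copy()
    pos = np.asarray(positions, dtype=float)
    for b in bad:
        d = np.linalg.norm(pos[good] - pos[b], axis=1)
        if np.any(d < 1e-12):
            out[b] = trial_data[good[int(np.argmin(d))]]
            continue
        w = 1.0 / d
        w /= w.sum()
        out[b] = w @ trial_data[good]
    return out


@dataclass
class RejectionReport:
    """Bookkeeping of the two-step rejection, in original trial indices."""

    electrode_thresholds: dict[str, float] = field(default_factory=dict)
    electrode_bad_trials: dict[str, list[int]] = field(default_factory=dict)
    trial_thresholds: dict[int, float] = field(default_factory=dict)
    trial_bad_electrodes: dict[int, list[str]] = field(default_factory=dict)
    interpolated: list[tuple[int, str]] = field(default_factory=list)
    excluded_trials: list[int] = field(default_factory=list)
    n_trials: int = 0
    n_scalp: int = 0

    @property
    def marked_pairs(self) -> set[tuple[int, str]]:
        pairs: set[tuple[int, str]] = set()
        for name, trials in self.electrode_bad_trials.items():
            pairs.update((t, name) for t in trials)
        for t, names in self.trial_bad_electrodes.items():
            pairs.update((t, n) for n in names)
        return pairs

    @property
    def rejection_rate(self) -> float:
        """Fraction of trial x electrode entries marked bad."""
        if self.n_trials == 0:
            return 0.0
        return len(self.marked_pairs) / (self.n_trials * self.n_scalp)

    @property
    def exclusion_rate(self) -> float:
        if self.n_trials == 0:
            return 0.0
        return len(self.excluded_trials) / self.n_trials

    def summary(self) -> dict:
        return {
            "n_trials": self.n_trials,
            "n_scalp": self.n_scalp,
            "n_excluded": len(self.excluded_trials),
            "n_interpolated_entries": len(self.interpolated),
            "rejection_rate": self.rejection_rate,
            "exclusion_rate": self.exclusion_rate,
        }


def _repair(
    data: np.ndarray,
    marked: dict[int, set[int]],
    scalp_idx: np.ndarray,
    positions: np.ndarray,
    n_scalp: int,
) -> tuple[set[int], list[tuple[int, int]]]:
    """Interpolate trials with < half scalp electrodes marked; list the rest.

    ``marked`` maps trial index (current array order) to a set of scalp
    electrode positions (0..n_scalp-1).  Returns (excluded trial
    indices, interpolated (trial, scalp_electrode) pairs).  ``data`` is
    modified in place.
    """
    excluded: set[int] = set()
    interpolated: list[tuple[int, int]] = []
    for tr, els in marked.items():
        if not els:
            continue
        if len(els) >= n_scalp / 2:
            excluded.add(tr)
            continue
        scalp_block = data[tr][scalp_idx]
        data[tr][scalp_idx] = interpolate_channels(scalp_block, els, positions)
        interpolated.extend((tr, e) for e in sorted(els))
    return excluded, interpolated


def two_step_rejection(
    ds: EpochedDataset,
) -> tuple[EpochedDataset, RejectionReport]:
    """Electrode-wise then trial-wise automatic rejection with repair.

    Pass 1 thresholds each scalp electrode's trials; pass 2 (run on the
    pass-1-repaired data, excluded trials dropped) thresholds each
    trial's scalp electrodes.  Interpolated entries are flagged in the
    returned dataset's ``bad_mask``; report indices refer to the input
    dataset's trial order.
    """
    if ds.n_trials < 2:
        raise ValueError("need at least 2 trials")
    scalp_idx = ds.scalp_indices
    n_scalp = len(scalp_idx)
    if n_scalp < 2:
        raise ValueError("need at least 2 scalp electrodes")
    positions = np.array([ds.channels[i].position for i in scalp_idx], dtype=float)
    scalp_names = [ds.channels[i].name for i in scalp_idx]

    data = ds.data.copy()
    bad_mask = np.zeros((ds.n_trials, ds.n_channels), dtype=bool)
    report = RejectionReport(n_trials=ds.n_trials, n_scalp=n_scalp)

    # -- pass 1: across trials, per electrode -------------------------
    marked1: dict[int, set[int]] = {t: set() for t in range(ds.n_trials)}
    for e_pos, (e, name) in enumerate(zip(scalp_idx, scalp_names)):
        thr, kept = auto_threshold(data[:, e, :])
        bad_trials = sorted(set(range(ds.n_trials)) - set(kept.tolist()))
        report.electrode_thresholds[name] = thr
        if bad_trials:
            report.electrode_bad_trials[name] = bad_trials
        for t in bad_trials:
            marked1[t].add(e_pos)

    excluded1, interp1 = _repair(data, marked1, scalp_idx, positions, n_scalp)
    for tr, e_pos in interp1:
        bad_mask[tr, scalp_idx[e_pos]] = True
        report.interpolated.append((tr, scalp_names[e_pos]))

    keep = np.array([t for t in range(ds.n_trials) if t not in excluded1], dtype=int)
    data = data[keep]
    bad_mask = bad_mask[keep]
    orig_index = keep                     # current position -> original trial

    # -- pass 2: across electrodes, per trial.  Channels interpolated in
    # pass 1 are already repaired and are excluded from the candidate
    # group: an interpolated channel is a weighted mean of the others,
    # so it sits unnaturally close to the median waveform and would
    # otherwise dominate the threshold objective.
    marked2: dict[int, set[int]] = {}
    for t in range(len(data)):
        eligible = np.flatnonzero(~bad_mask[t][scalp_idx])
        if len(eligible) < 2:
            continue
        thr, kept_rel = auto_threshold(data[t][scalp_idx[eligible]])
        kept_els = eligible[kept_rel]
        bad_els = sorted(set(eligible.tolist()) - set(kept_els.tolist()))
        report.trial_thresholds[int(orig_index[t])] = thr
        if bad_els:
            report.trial_bad_electrodes[int(orig_index[t])] = [
                scalp_names[e] for e in bad_els
            ]
            marked2[t] = set(bad_els)

    excluded2, interp2 = _repair(data, marked2, scalp_idx, positions, n_scalp)
    for tr, e_pos in interp2:
        bad_mask[tr, scalp_idx[e_pos]] = True
        report.interpolated.append((int(orig_index[tr]), scalp_names[e_pos]))

    report.excluded_trials = sorted(
        [int(t) for t in excluded1] + [int(orig_index[t]) for t in excluded2]
    )

    keep2 = np.array([t for t in range(len(data)) if t not in excluded2], dtype=int)
    out = EpochedDataset(
        data=data[keep2],
        times=ds.times.copy(),
        sfreq=ds.sfreq,
        labels=ds.labels[orig_index[keep2]].copy(),
        channels=list(ds.channels),
        subject_id=ds.subject_id,
        conditions=ds.conditions,
        bad_mask=bad_mask[keep2],
    )
    return out, report
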