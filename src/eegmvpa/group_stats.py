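"""Group-level inference on decoding maps.

The test statistic is the group-mean accuracy map minus chance (0.5),
enhanced with threshold-free cluster enhancement (TFCE):

    TFCE(p) = sum_{h = dh, 2dh, ... <= v(p)}  e(p, h)^E * h^H * dh

where ``e(p, h)`` is the size of the contiguous suprathreshold
component at height h containing point p, with E = 0.5, H = 2 and an
adaptive step dh = range/100.  Negative values are handled by
transforming the positive and negative parts separately and
recombining with sign, so the transform is odd: TFCE(-x) = -TFCE(x).

Familywise error is controlled with a maximal-statistic permutation
null: condition labels are permuted across trials within each subject,
per-subject accuracy maps are recomputed, group-averaged and
TFCE-transformed, and the maximum (and minimum, for the negative tail)
over all points is recorded per permutation.  Observed TFCE values are
converted to z via rank-based p-values with +1 smoothing,

    p+ = (1 + #{null_max >= obs}) / (n_perm + 1),

z = Phi^{-1}(1 - p) signed by the dominant tail; with 100 permutations
the attainable |z| caps at Phi^{-1}(100/101) = 2.33.  Because the
cross-validation fold assignment is itself a random choice, the whole
analysis is repeated (default 20 times) and the resulting z-maps are
averaged; significance is read off the averaged map at |z| > 1.96.

For comparing two decoding analyses on the same subjects (e.g. hands
vs. X against tools vs. X), the per-subject accuracy difference is
tested with the same TFCE machinery under a subject-level sign-flip
null — the natural exchangeable unit for a paired comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import ndimage
from scipy.stats import norm

Z_CRIT_DEFAULT = 1.96


@dataclass(frozen=True)
class TFCEParams:
    E: float = 0.5
    H: float = 2.0
    dh: float | None = None     # None -> adaptive: (range incl. 0) / n_steps
    n_steps: int = 100

    def __post_init__(self) -> None:
        if self.E < 0 or self.H < 0:
            raise ValueError("E and H must be >= 0")
        if self.dh is not None and self.dh <= 0:
            raise ValueError("dh must be > 0")


def _tfce_one_sided(values: np.ndarray, E: float, H: float, dh: float) -> np.ndarray:
    out = np.zeros_like(values, dtype=float)
    vmax = values.max() if values.size else 0.0
    if vmax <= 0 or dh <= 0:
        return out
    n_heights = int(np.floor(vmax / dh + 1e-9))
    for i in range(1, n_heights + 1):
        h = i * dh
        mask = values >= h
        labels, n_comp = ndimage.label(mask)   # 2-neighbor (1-D) / 4-neighbor (2-D)
        if n_comp == 0:
            continue
        sizes = np.bincount(labels.ravel())
        out[mask] += sizes[labels[mask]] ** E * h**H * dh
    return out


def tfce_transform(
    values: np.ndarray, params: TFCEParams = TFCEParams()
) -> np.ndarray:
    """TFCE of a 1-D or 2-D map; odd in its argument."""
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("map contains non-finite values")
    if params.dh is not None:
        dh = params.dh
    else:
        span = max(values.max(), 0.0) - min(values.min(), 0.0)
        dh = span / params.n_steps
    pos = _tfce_one_sided(values, params.E, params.H, dh)
    neg = _tfce_one_sided(-values, params.E, params.H, dh)
    return pos - neg


# ---------------------------------------------------------------------
# permutation null and z conversion
# ---------------------------------------------------------------------

def group_tfce(
    subject_maps: np.ndarray, baseline: float = 0.5,
    params: TFCEParams = TFCEParams(),
) -> np.ndarray:
    """TFCE of the group-mean map after baseline subtraction."""
    return tfce_transform(np.mean(subject_maps, axis=0) - baseline, params)


def build_permutation_null(
    subject_maps_fn: Callable[[np.random.Generator], np.ndarray],
    n_perm: int = 100,
    seed: int = 0,
    baseline: float = 0.5,
    params: TFCEParams = TFCEParams(),
) -> tuple[np.ndarray, np.ndarray]:
    """Maximal-statistic null over label permutations.

    ``subject_maps_fn(rng)`` must recompute every subject's accuracy
    map under a label permutation drawn from ``rng`` (independent draws
    per subject) and return them stacked as (n_subjects, ...).  Returns
    the per-permutation maxima and minima of the TFCE-transformed
    group map.
    """
    null_max = np.empty(n_perm)
    null_min = np.empty(n_perm)
    for i in range(n_perm):
        rng = np.random.default_rng([seed, i])
        maps = np.asarray(subject_maps_fn(rng))
        if maps.shape[0] < 2:
            raise ValueError("need at least 2 subjects")
        t = group_tfce(maps, baseline, params)
        null_max[i] = t.max()
        null_min[i] = t.min()
    return null_max, null_min


@dataclass
class Cluster:
    """A maximal contiguous significant region of a z-map."""

    indices: np.ndarray          # flat indices into the map
    onset: float                 # first significant time (1-D: ms)
    offset: float                # last significant time (1-D: ms)
    peak_index: tuple[int, ...]
    peak_time: float | tuple[float, float]
    peak_z: float
    peak_accuracy: float | None
    sign: int                    # sign of z at the peak


@dataclass
class ZMap:
    """TFCE-permutation z-scores with significance mask and clusters."""

    z: np.ndarray
    times: np.ndarray                       # 1-D axis, or train-time axis (2-D)
    z_crit: float = Z_CRIT_DEFAULT
    times_test: np.ndarray | None = None    # test-time axis for 2-D maps
    accuracy: np.ndarray | None = None      # underlying group-mean accuracy
    clusters: list[Cluster] = field(default_factory=list)

    @property
    def mask(self) -> np.ndarray:
        return np.abs(self.z) > self.z_crit

    def finalize(self) -> "ZMap":
        self.clusters = extract_clusters(
            self.z, self.times, self.z_crit, self.times_test, self.accuracy
        )
        return self


def z_from_null(
    observed_tfce: np.ndarray,
    null_max: np.ndarray,
    null_min: np.ndarray,
    times: np.ndarray | None = None,
    times_test: np.ndarray | None = None,
    accuracy: np.ndarray | None = None,
    z_crit: float = Z_CRIT_DEFAULT,
) -> ZMap:
    """Rank-based two-tailed z-map against the max-statistic null.

    Per point, p+ ranks the observed value in the null maxima and p-
    in the null minima (+1 smoothing); the z value is the normal
    quantile of the dominant tail, zero where neither tail reaches
    p < 0.5.  Monotone: a larger observed TFCE never yields a smaller z.
    """
    observed = np.asarray(observed_tfce, dtype=float)
    n = len(null_max)
    p_plus = (1 + np.sum(null_max[:, None] >= observed.ravel()[None, :], axis=0)) / (
        n + 1
    )
    p_minus = (1 + np.sum(null_min[:, None] <= observed.ravel()[None, :], axis=0)) / (
        n + 1
    )
    zp = norm.ppf(1.0 - p_plus)
    zm = norm.ppf(1.0 - p_minus)
    z = (np.maximum(zp, 0.0) - np.maximum(zm, 0.0)).reshape(observed.shape)
    zmap = ZMap(
        z=z,
        times=np.arange(observed.shape[0]) if times is None else np.asarray(times),
        z_crit=z_crit,
        times_test=None if times_test is None else np.asarray(times_test),
        accuracy=accuracy,
    )
    return zmap.finalize()


def repeat_and_average_zmaps(
    analysis_fn: Callable[[int], ZMap],
    n_repetitions: int = 20,
    z_crit: float = Z_CRIT_DEFAULT,
) -> ZMap:
    """Average the z-maps of repeated analyses; re-threshold the mean.

    ``analysis_fn(rep)`` runs one complete analysis (fresh fold
    assignment and permutation null) and returns its ZMap.
    """
    zmaps = [analysis_fn(rep) for rep in range(n_repetitions)]
    z = np.mean([m.z for m in zmaps], axis=0)
    accs = [m.accuracy for m in zmaps if m.accuracy is not None]
    acc = np.mean(accs, axis=0) if accs else None
    out = ZMap(
        z=z,
        times=zmaps[0].times,
        z_crit=z_crit,
        times_test=zmaps[0].times_test,
        accuracy=acc,
    )
    return out.finalize()


def paired_accuracy_difference(
    acc_a: np.ndarray,
    acc_b: np.ndarray,
    times: np.ndarray,
    n_perm: int = 100,
    seed: int = 0,
    params: TFCEParams = TFCEParams(),
    z_crit: float = Z_CRIT_DEFAULT,
) -> ZMap:
    """Paired test of two per-subject accuracy maps (A minus B).

    ``acc_a`` and ``acc_b`` are (n_subjects, n_times) from the same
    subjects.  The null swaps the A/B assignment within each subject
    (a sign flip of the difference).  Positive z means A > B.  With a
    shared seed, swapping the inputs exactly negates the z-map.
    """
    acc_a = np.asarray(acc_a, dtype=float)
    acc_b = np.asarray(acc_b, dtype=float)
    if acc_a.shape != acc_b.shape:
        raise ValueError(f"shape mismatch: {acc_a.shape} vs {acc_b.shape}")
    diff = acc_a - acc_b                       # (n_subjects, n_times)
    n_subj = diff.shape[0]
    observed = tfce_transform(diff.mean(axis=0), params)
    null_max = np.empty(n_perm)
    null_min = np.empty(n_perm)
    for i in range(n_perm):
        rng = np.random.default_rng([seed, i])
        signs = rng.choice([-1.0, 1.0], size=n_subj)
        t = tfce_transform((signs[:, None] * diff).mean(axis=0), params)
        null_max[i] = t.max()
        null_min[i] = t.min()
    return z_from_null(
        observed, null_max, null_min, times=times,
        accuracy=diff.mean(axis=0), z_crit=z_crit,
    )


def extract_clusters(
    z: np.ndarray,
    times: np.ndarray,
    z_crit: float = Z_CRIT_DEFAULT,
    times_test: np.ndarray | None = None,
    accuracy: np.ndarray | None = None,
) -> list[Cluster]:
    """Maximal contiguous |z| > z_crit regions, with peak bookkeeping.

    1-D maps use 2-neighbor contiguity, 2-D maps 4-neighbor (no
    diagonals).  Onset is the first timepoint in the cluster (train
    time, for 2-D maps).
    """
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("z-map contains non-finite values")
    mask = np.abs(z) > z_crit
    labels, n_comp = ndimage.label(mask)
    times = np.asarray(times)
    clusters: list[Cluster] = []
    for c in range(1, n_comp + 1):
        flat = np.flatnonzero(labels.ravel() == c)
        zvals = z.ravel()[flat]
        peak_flat = flat[np.argmax(np.abs(zvals))]
        peak_index = np.unravel_index(peak_flat, z.shape)
        axis0 = np.unique(np.unravel_index(flat, z.shape)[0])
        if z.ndim == 1:
            peak_time: float | tuple[float, float] = float(times[peak_index[0]])
        else:
            tt = times if times_test is None else times_test
            peak_time = (float(times[peak_index[0]]), float(tt[peak_index[1]]))
        clusters.append(
            Cluster(
                indices=flat,
                onset=float(times[axis0[0]]),
                offset=float(times[axis0[-1]]),
                peak_index=tuple(int(i) for i in peak_index),
                peak_time=peak_time,
                peak_z=float(z.ravel()[peak_flat]),
                peak_accuracy=(
                    None if accuracy is None else float(accuracy.ravel()[peak_flat])
                ),
                sign=int(np.sign(z.ravel()[peak_flat])),
            )
        )
    return clusters
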