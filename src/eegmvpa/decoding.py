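"""Per-timepoint LDA decoding, cross-classification and temporal generalization.

At each timepoint the feature vector is the pattern across scalp
channels.  Features are z-scored with statistics estimated on the
training trials only (the same transform is applied to test trials, so
nothing leaks), then classified with a two-class linear discriminant:

    S      = (1 - lam) * S_pooled + lam * (tr(S_pooled)/p) * I
    w      = S^{-1} (mu_1 - mu_0),    b = -w . (mu_0 + mu_1) / 2

with equal priors (folds are balanced by construction) and shrinkage
intensity ``lam`` — by default a Ledoit-Wolf-style analytic estimate
toward the scaled identity, since 63 channels vs. ~200 training trials
makes the raw pooled covariance ill-conditioned.  A discriminant score
of exactly zero is assigned to the control class.

Standard decoding uses balanced k-fold cross-validation (k = 10):
each class is truncated to a common size divisible by k, and every fold
holds the same number of trials of each class.  The whole procedure is
repeated (default 20 times) with fresh fold assignments and balancing
subsamples; per-repetition accuracies are kept separate so group
statistics can average z-maps over repetitions.

Cross-classification trains on ALL balanced trials of a condition pair
(no folds needed — the test condition is disjoint from the training
pair) and scores the fraction of test-condition trials classified as
the training target, so 0.5 means no bias toward either trained class.
Temporal generalization applies the classifier trained at t_train to
test features at every t_test; test features at t_test are standardized
with the training statistics computed at t_test, so only the
classifier, not the scaler, crosses time.  The TG diagonal therefore
reproduces the cross-classification timecourse exactly under a shared
seed.

All internal fits are vectorized across timepoints (stacked solves),
which is what makes permutation-based group inference tractable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .data_model import ConditionPair, EpochedDataset, select_conditions

logger = logging.getLogger(__name__)

Shrinkage = float | str   # explicit lambda in [0, 1] or "ledoit-wolf"


# ---------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------

def zscore_train_apply(
    train: np.ndarray, test: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Standardize per feature using training statistics only.

    ``train`` is (n_train, p), ``test`` (n_test, p).  Zero-variance
    features get sd 1 (flagged in the log), yielding zeros after
    centering rather than an exception.
    """
    train = np.asarray(train, dtype=float)
    test = np.asarray(test, dtype=float)
    mean = train.mean(axis=0)
    sd = train.std(axis=0)
    flat = sd == 0
    if flat.any():
        logger.warning("zscore: %d zero-variance feature(s) flagged", flat.sum())
        sd = np.where(flat, 1.0, sd)
    return (train - mean) / sd, (test - mean) / sd


@dataclass
class LDAModel:
    """Fitted two-class linear discriminant in z-space."""

    means: np.ndarray        # (2, p): class 0 (control), class 1 (target)
    covariance: np.ndarray   # (p, p) shrunk pooled covariance
    shrinkage: float
    w: np.ndarray            # (p,)
    b: float

    def decision(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.w + self.b

    def predict(self, X: np.ndarray) -> np.ndarray:
        """1 for the target class; score exactly 0 -> control (0)."""
        return (self.decision(X) > 0).astype(int)


def _ledoit_wolf_lambda(sq_norms_c: np.ndarray, S_n: np.ndarray) -> np.ndarray:
    """Batched Ledoit-Wolf shrinkage toward the scaled identity.

    ``sq_norms_c`` is (B, n): squared norms of the centered samples;
    ``S_n`` the (B, p, p) covariance with denominator n.  Returns
    lambda per batch element, clipped to [0, 1].
    """
    B, n = sq_norms_c.shape
    p = S_n.shape[-1]
    S_n = S_n.astype(np.float64, copy=False)
    sq = sq_norms_c.astype(np.float64, copy=False)
    m = np.trace(S_n, axis1=1, axis2=2) / p                      # (B,)
    eye = np.eye(p)
    d2 = np.sum((S_n - m[:, None, None] * eye) ** 2, axis=(1, 2)) / p
    frob_S = np.sum(S_n**2, axis=(1, 2))
    b2 = (np.sum(sq**2, axis=1) - n * frob_S) / (n**2 * p)
    with np.errstate(divide="ignore", invalid="ignore"):
        lam = np.where(d2 > 0, np.minimum(b2, d2) / np.where(d2 > 0, d2, 1.0), 0.0)
    return np.clip(lam, 0.0, 1.0)


def _batched_lda(
    X: np.ndarray, y: np.ndarray, shrinkage: Shrinkage
) -> tuple[np.ndarray, np.ndarray]:
    """Fit the discriminant for a whole batch of training sets at once.

    ``X`` is (B, n, p) z-scored training data — the batch axis B may
    stack timepoints, folds and subjects.  ``y`` is binary labels,
    either (n,) shared across the batch or (B, n).  Returns (W, b)
    with W (B, p) and b (B,).
    """
    B, n, p = X.shape
    y = np.asarray(y, dtype=X.dtype)
    if y.ndim == 1:
        y = np.broadcast_to(y, (B, n))
    n1 = y.sum(axis=1)                                  # (B,)
    n0 = n - n1
    mu0 = np.einsum("bn,bnp->bp", 1.0 - y, X) / n0[:, None]
    mu1 = np.einsum("bn,bnp->bp", y, X) / n1[:, None]
    # within-class scatter via a rank-one update of the Gram matrix,
    # avoiding materialization of the centered (B, n, p) block
    G = np.matmul(X.transpose(0, 2, 1), X)
    scatter = (
        G
        - n0[:, None, None] * (mu0[:, :, None] * mu0[:, None, :])
        - n1[:, None, None] * (mu1[:, :, None] * mu1[:, None, :])
    )
    S = scatter.astype(np.float64) / (n - 2)    # unbiased pooled covariance
    if shrinkage == "ledoit-wolf":
        # ||x_k - mu_{y_k}||^2 from uncentered pieces
        sq_norms = np.einsum("bnp,bnp->bn", X, X)
        proj = y * np.einsum("bnp,bp->bn", X, mu1) + (1.0 - y) * np.einsum(
            "bnp,bp->bn", X, mu0
        )
        mu_sq = y * np.sum(mu1**2, axis=1)[:, None] + (1.0 - y) * np.sum(
            mu0**2, axis=1
        )[:, None]
        lam = _ledoit_wolf_lambda(sq_norms - 2.0 * proj + mu_sq, scatter / n)
    else:
        lam = np.full(B, float(shrinkage))
    m = np.trace(S, axis1=1, axis2=2) / p
    eye = np.eye(p)
    S_shr = (1.0 - lam)[:, None, None] * S + (lam * m)[:, None, None] * eye
    mu0 = mu0.astype(np.float64)
    mu1 = mu1.astype(np.float64)
    W = np.linalg.solve(S_shr, (mu1 - mu0)[..., None])[..., 0]
    b = -np.einsum("bp,bp->b", W, (mu0 + mu1) / 2.0)
    return W, b


def lda_fit(X: np.ndarray, y: np.ndarray, shrinkage: Shrinkage = 0.0) -> LDAModel:
    """Fit a single two-class shrinkage LDA (thin wrapper on the batched path)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if X.ndim != 2:
        raise ValueError("X must be (n_samples, n_features)")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite values")
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("need exactly two classes in y")
    n, p = X.shape
    mu0, mu1 = X[y == 0].mean(axis=0), X[y == 1].mean(axis=0)
    Xc = np.where((y == 0)[:, None], X - mu0, X - mu1)
    scatter = Xc.T @ Xc
    S = scatter / (n - 2)
    if shrinkage == "ledoit-wolf":
        lam = float(_ledoit_wolf_lambda(Xc[None], (scatter / n)[None])[0])
    else:
        lam = float(shrinkage)
    S_shr = (1 - lam) * S + lam * (np.trace(S) / p) * np.eye(p)
    w = np.linalg.solve(S_shr, mu1 - mu0)
    b = float(-w @ (mu0 + mu1) / 2.0)
    return LDAModel(
        means=np.stack([mu0, mu1]), covariance=S_shr, shrinkage=lam, w=w, b=b
    )


def make_balanced_folds(labels: np.ndarray, k: int, seed) -> np.ndarray:
    """Balanced fold assignment; -1 marks trials left out by truncation.

    Each class is truncated (random subsample) to the largest size
    divisible by k, and every fold receives class_count/k trials of
    each class.  Deterministic given the seed.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    folds = np.full(len(labels), -1, dtype=int)
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < k:
            raise ValueError(f"class {cls!r} has {len(idx)} trials, fewer than k={k}")
        m = (len(idx) // k) * k
        chosen = rng.permutation(idx)[:m]
        folds[chosen] = np.repeat(np.arange(k), m // k)
    return folds


# ---------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------

@dataclass
class DecodingTimecourse:
    """Per-repetition, per-timepoint classification accuracy."""

    accuracies: np.ndarray          # (n_repetitions, n_times), in [0, 1]
    times: np.ndarray               # ms
    pair: ConditionPair
    k: int
    seed: int
    chance: float = 0.5
    fold_assignments: np.ndarray | None = None   # (n_repetitions, n_trials)
    test_condition: str | None = None            # set for cross-classification

    @property
    def mean_accuracy(self) -> np.ndarray:
        return self.accuracies.mean(axis=0)


@dataclass
class TGMatrix:
    """Train-time x test-time cross-classification scores.

    ``values[r, i, j]`` is the fraction of test-condition trials that
    the classifier trained at time i (repetition r) assigns to the
    training target class when applied at time j.
    """

    values: np.ndarray              # (n_repetitions, n_times, n_times)
    times: np.ndarray
    train_pair: ConditionPair
    test_condition: str
    seed: int

    @property
    def mean_values(self) -> np.ndarray:
        return self.values.mean(axis=0)

    @property
    def diagonal(self) -> np.ndarray:
        """(n_repetitions, n_times) matched-time cross-classification."""
        return np.diagonal(self.values, axis1=1, axis2=2)


# ---------------------------------------------------------------------
# decoding drivers
# ---------------------------------------------------------------------

def _features(ds: EpochedDataset, conditions) -> tuple[np.ndarray, np.ndarray]:
    """Scalp-channel features (T, n, p) and labels for given conditions.

    Features are cast to float32: the decoding path is throughput-bound
    and single precision is far more than the effective SNR of EEG.
    """
    sub = select_conditions(ds, list(conditions))
    X = sub.data[:, sub.scalp_indices, :]       # (n, p, T)
    return np.ascontiguousarray(X.transpose(2, 0, 1), dtype=np.float32), sub.labels


def _zscore_batched(
    train: np.ndarray, test: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """(B, n, p) version of :func:`zscore_train_apply`."""
    n = train.shape[1]
    mean = train.mean(axis=1, keepdims=True)
    sq = np.einsum("bnp,bnp->bp", train, train)[:, None, :] / n
    var = np.maximum(sq - mean**2, 0.0)
    # one-pass variance cancels catastrophically for (near-)constant
    # features; flag them flat relative to the raw second moment
    eps = 1e-4 if train.dtype == np.float32 else 1e-12
    sd = np.sqrt(var)
    sd = np.where(var <= eps * sq, 1.0, sd)
    inv = 1.0 / sd
    return (train - mean) * inv, (test - mean) * inv


def decode_timecourse(
    ds: EpochedDataset,
    pair: ConditionPair,
    k: int = 10,
    n_repetitions: int = 20,
    shrinkage: Shrinkage = "ledoit-wolf",
    seed: int = 0,
    permute_labels_rng: np.random.Generator | None = None,
) -> DecodingTimecourse:
    """Cross-validated per-timepoint decoding of a condition pair.

    ``permute_labels_rng``, if given, shuffles the condition labels of
    the selected trials before decoding — the within-subject label
    permutation used to build group-level nulls.
    """
    X, labels = _features(ds, pair)
    y = (labels == pair.target).astype(int)
    if permute_labels_rng is not None:
        y = permute_labels_rng.permutation(y)
    T, _, p = X.shape
    accuracies = np.empty((n_repetitions, T))
    assignments = np.empty((n_repetitions, len(y)), dtype=int)
    for rep in range(n_repetitions):
        folds = make_balanced_folds(y, k, seed=[seed, rep])
        assignments[rep] = folds
        tr_idx = [np.flatnonzero((folds >= 0) & (folds != f)) for f in range(k)]
        te_idx = [np.flatnonzero(folds == f) for f in range(k)]
        n_tr = len(tr_idx[0])
        # process folds in groups so the stacked (folds*T, n_tr, p)
        # training block stays within a modest memory footprint
        per_fold = T * n_tr * p
        group = max(1, min(k, int(8e6 // max(per_fold, 1))))
        fold_acc = np.zeros(T)
        for start in range(0, k, group):
            fs = range(start, min(start + group, k))
            g = len(fs)
            Xtr = np.stack([X[:, tr_idx[f]] for f in fs])      # (g, T, n_tr, p)
            Xte = np.stack([X[:, te_idx[f]] for f in fs])
            ytr = np.stack([
                np.broadcast_to(y[tr_idx[f]], (T, n_tr)) for f in fs
            ]).reshape(g * T, n_tr)
            Ztr, Zte = _zscore_batched(
                Xtr.reshape(g * T, n_tr, p),
                Xte.reshape(g * T, -1, p),
            )
            W, b = _batched_lda(Ztr, ytr, shrinkage)
            scores = np.einsum("bnp,bp->bn", Zte, W) + b[:, None]
            pred = (scores > 0).reshape(g, T, -1)
            yte = np.stack([y[te_idx[f]] == 1 for f in fs])     # (g, n_te)
            fold_acc += (pred == yte[:, None, :]).mean(axis=2).sum(axis=0)
        accuracies[rep] = fold_acc / k
    return DecodingTimecourse(
        accuracies=accuracies,
        times=ds.times.copy(),
        pair=pair,
        k=k,
        seed=seed,
        fold_assignments=assignments,
    )


def _cross_models(
    ds: EpochedDataset,
    train_pair: ConditionPair,
    test_condition: str,
    shrinkage: Shrinkage,
    rep_seed,
    permute_labels_rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Train per-timepoint models on the full balanced pair; z-score test.

    Returns (W, b, Ztest): W (T, p), b (T,), Ztest (T, n_test, p) with
    test features standardized by the training statistics of the SAME
    timepoint.
    """
    if test_condition in (train_pair.target, train_pair.control):
        raise ValueError("test condition must be disjoint from the training pair")
    Xtr, labels = _features(ds, train_pair)
    y = (labels == train_pair.target).astype(int)
    if permute_labels_rng is not None:
        y = permute_labels_rng.permutation(y)
    Xte, te_labels = _features(ds, [test_condition])
    if Xte.shape[1] == 0:
        raise ValueError(f"no trials of test condition {test_condition!r}")

    # balanced subsample of the training pair, redrawn per repetition
    rng = np.random.default_rng(rep_seed)
    i0, i1 = np.flatnonzero(y == 0), np.flatnonzero(y == 1)
    m = min(len(i0), len(i1))
    sel = np.sort(
        np.concatenate([
            rng.permutation(i0)[:m], rng.permutation(i1)[:m]
        ])
    )
    Xtr, y = Xtr[:, sel], y[sel]

    Ztr, Zte = _zscore_batched(Xtr, Xte)
    W, b = _batched_lda(Ztr, y, shrinkage)
    return W, b, Zte


def cross_classify_timecourse(
    ds: EpochedDataset,
    train_pair: ConditionPair,
    test_condition: str,
    n_repetitions: int = 20,
    shrinkage: Shrinkage = "ledoit-wolf",
    seed: int = 0,
    permute_labels_rng: np.random.Generator | None = None,
) -> DecodingTimecourse:
    """Train on a pair, test on a third condition, per timepoint.

    The score at each timepoint is the fraction of test-condition
    trials classified as the training target; 0.5 means no bias toward
    either trained class.
    """
    reps = []
    for rep in range(n_repetitions):
        W, b, Zte = _cross_models(
            ds, train_pair, test_condition, shrinkage, [seed, rep],
            permute_labels_rng,
        )
        scores = np.einsum("tnp,tp->tn", Zte, W) + b[:, None]
        reps.append((scores > 0).mean(axis=1))
    return DecodingTimecourse(
        accuracies=np.stack(reps),
        times=ds.times.copy(),
        pair=train_pair,
        k=0,
        seed=seed,
        test_condition=test_condition,
    )


def temporal_generalization(
    ds: EpochedDataset,
    train_pair: ConditionPair,
    test_condition: str,
    n_repetitions: int = 20,
    shrinkage: Shrinkage = "ledoit-wolf",
    seed: int = 0,
) -> TGMatrix:
    """Apply each train-time classifier at every test timepoint.

    Shares its per-repetition training subsample with
    :func:`cross_classify_timecourse`, so the TG diagonal equals the
    cross-classification timecourse exactly for the same seed.
    """
    reps = []
    for rep in range(n_repetitions):
        W, b, Zte = _cross_models(
            ds, train_pair, test_condition, shrinkage, [seed, rep]
        )
        scores = np.einsum("ap,bnp->abn", W, Zte) + b[:, None, None]
        reps.append((scores > 0).mean(axis=2))
    return TGMatrix(
        values=np.stack(reps),
        times=ds.times.copy(),
        train_pair=train_pair,
        test_condition=test_condition,
        seed=seed,
    )
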