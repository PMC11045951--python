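"""Evaluation battery: reconstruction, NRMSE, RDM/RSA, decoding, statistics.

"Responses" throughout are window-mean traces (the same statistic the
learning rule uses).  Representational dissimilarity matrices (RDMs) use
1 - Spearman rank correlation as the distance; second-order RSA compares two
RDMs by the Spearman correlation of their strict upper triangles, making it
invariant to any monotone transform of either RDM's entries.  Decoding uses
a multinomial logistic-regression readout; group comparisons use the
two-sided Mann-Whitney U test with bootstrap confidence intervals on the
means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .network import PCNetwork
from .simulation import RecordingBuffer

__all__ = [
    "RDM",
    "DecodingResult",
    "GroupComparison",
    "reconstruct",
    "nrmse",
    "compute_rdm",
    "second_order_rsa",
    "decode",
    "resample_test_sets",
    "compare_groups",
]


@dataclass
class RDM:
    """Pairwise dissimilarities 1 - Spearman rho between item responses.

    Square, symmetric, zero diagonal; defined entries lie in [0, 2].
    Entries involving a constant response (undefined ranks) are NaN and the
    offending items are listed in ``flagged``.
    """

    matrix: np.ndarray
    labels: np.ndarray | None = None
    flagged: list[int] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(self.n, k=1)
        return self.matrix[iu]


@dataclass
class DecodingResult:
    """Classifier accuracy over resampled test sets for one condition."""

    accuracies: np.ndarray
    group: str = ""

    @property
    def n_resamples(self) -> int:
        return self.accuracies.shape[0]

    @property
    def mean(self) -> float:
        return float(self.accuracies.mean())


@dataclass
class GroupComparison:
    """Two-sided Mann-Whitney U with bootstrap 95% CIs of each mean."""

    U: float
    p_value: float
    ci_a: tuple[float, float]
    ci_b: tuple[float, float]


def reconstruct(
    net: PCNetwork, window_means: RecordingBuffer | dict, from_area: int
) -> np.ndarray:
    """Map an area's window-mean representation down to input dimensionality.

    Chains the transposed tied weights: from_area=1 gives the direct
    top-down prediction (W^{0,1})^T mean_X_R^1; higher areas compose the
    per-step predictions, e.g. (W^{0,1})^T (W^{1,2})^T mean_X_R^2.
    """
    wm = window_means.window_means if isinstance(window_means, RecordingBuffer) \
        else window_means
    if not (1 <= from_area <= net.top):
        raise ValueError(f"from_area must be in [1, {net.top}]")
    v = np.asarray(wm[f"R{from_area}"], dtype=float)
    for l in range(from_area - 1, -1, -1):
        v = net.W_inter[l].values.T @ v
    return v


def nrmse(target: np.ndarray, prediction: np.ndarray) -> float:
    """Root-mean-square error normalised by the target's range (max - min).

    Range normalisation makes the measure scale-free: applying one affine
    map to both target and prediction leaves it unchanged.
    """
    target = np.asarray(target, dtype=float)
    prediction = np.asarray(prediction, dtype=float)
    if target.shape != prediction.shape:
        raise ValueError("target and prediction must have equal length")
    rng = target.max() - target.min()
    if rng == 0:
        raise ValueError("target is constant; NRMSE undefined")
    return float(np.sqrt(np.mean((target - prediction) ** 2)) / rng)


def compute_rdm(responses, labels=None) -> RDM:
    """RDM of 1 - Spearman rank correlation between population responses.

    Ties receive average ranks.  Constant responses have no defined ranks;
    their rows/columns are NaN-flagged rather than silently zeroed.
    """
    R = np.asarray(responses, dtype=float)
    if R.ndim != 2 or R.shape[0] < 2:
        raise ValueError("need at least two equal-length responses")
    n = R.shape[0]
    flagged = [i for i in range(n) if np.ptp(R[i]) == 0]
    ranks = np.apply_along_axis(stats.rankdata, 1, R)
    with np.errstate(invalid="ignore"):
        C = np.corrcoef(ranks)
    D = 1.0 - C
    np.fill_diagonal(D, 0.0)
    for i in flagged:
        D[i, :] = np.nan
        D[:, i] = np.nan
        D[i, i] = 0.0
    if flagged:
        warnings.warn(
            f"constant responses at indices {flagged}: RDM entries undefined",
            RuntimeWarning,
            stacklevel=2,
        )
    return RDM(matrix=D, labels=None if labels is None else np.asarray(labels),
               flagged=flagged)


def second_order_rsa(rdm_a: RDM, rdm_b: RDM) -> float:
    """Spearman correlation between the two RDMs' strict upper triangles."""
    if rdm_a.matrix.shape != rdm_b.matrix.shape:
        raise ValueError("RDMs must have the same shape")
    if (rdm_a.labels is not None and rdm_b.labels is not None
            and not np.array_equal(rdm_a.labels, rdm_b.labels)):
        raise ValueError("RDMs must share item ordering")
    rho, _ = stats.spearmanr(rdm_a.upper_triangle(), rdm_b.upper_triangle())
    return float(rho)


def decode(
    train_features,
    train_labels,
    test_sets,
    group: str = "",
    seed: int = 0,
) -> DecodingResult:
    """Fit a multinomial linear readout once; score it on each test set.

    ``test_sets`` is an iterable of (features, labels) pairs, e.g. the
    resamples produced by :func:`resample_test_sets`.  The classifier is
    L2-penalised multinomial logistic regression with a fixed seed.
    """
    from sklearn.linear_model import LogisticRegression

    y = np.asarray(train_labels)
    if np.unique(y).size < 2:
        raise ValueError("decoding needs at least two classes in training data")
    clf = LogisticRegression(max_iter=5000, random_state=seed)
    clf.fit(np.asarray(train_features, dtype=float), y)
    accs = [clf.score(np.asarray(X, dtype=float), np.asarray(t))
            for X, t in test_sets]
    return DecodingResult(accuracies=np.array(accs), group=group)


def resample_test_sets(
    pool_features,
    pool_labels,
    n_sets: int = 100,
    set_size: int | None = None,
    seed: int = 0,
):
    """Randomly resample test sets from a held-out pool (with replacement
    across sets, without replacement within a set)."""
    X = np.asarray(pool_features, dtype=float)
    y = np.asarray(pool_labels)
    set_size = set_size or y.shape[0]
    if set_size > y.shape[0]:
        raise ValueError("set_size exceeds pool size")
    rng = np.random.default_rng(seed)
    for _ in range(n_sets):
        idx = rng.choice(y.shape[0], size=set_size, replace=False)
        yield X[idx], y[idx]


def compare_groups(
    a,
    b,
    n_boot: int = 2000,
    seed: int = 0,
) -> GroupComparison:
    """Two-sided Mann-Whitney U (normal approximation, tie-corrected) and
    percentile-bootstrap 95% confidence intervals of each group mean."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    rng = np.random.default_rng(seed)

    def ci(x: np.ndarray) -> tuple[float, float]:
        means = rng.choice(x, size=(n_boot, x.size), replace=True).mean(axis=1)
        lo, hi = np.percentile(means, [2.5, 97.5])
        return float(lo), float(hi)

    return GroupComparison(
        U=float(res.statistic), p_value=float(res.pvalue), ci_a=ci(a), ci_b=ci(b)
    )
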