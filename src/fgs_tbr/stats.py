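"""Self-contained nonparametric two-sample machinery.

Implements the Mann-Whitney rank-sum test (midranks for ties, tie-corrected
normal approximation with continuity correction, exact enumeration for small
samples) and empirical ROC curves with trapezoidal AUC and the Youden
operating point.  These primitives back both the cohort-level TBR comparison
and the pixel-level classifier validation, so they are written once here and
shared.

The rank-sum U statistic counts favorable pairs,

    U = sum_{i,j} [x_i > y_j] + 1/2 [x_i == y_j],

which ties it to the empirical AUC through U = AUC * n1 * n2 — an identity
the test suite asserts to near machine precision.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, rankdata

__all__ = ["RankSumResult", "ROCCurve", "rank_sum_test", "roc_curve", "optimal_threshold"]

# Exact enumeration is used for small samples; beyond this many splits the
# tie-corrected normal approximation takes over regardless of the size rule.
MAX_EXACT_SPLITS = 200_000


@dataclass(frozen=True)
class RankSumResult:
    """Two-sample rank-sum test outcome.

    u_statistic counts pairs (x_i, y_j) favorable to x (ties count 1/2);
    z_value is the tie-corrected standard-normal deviate, positive when x
    tends larger.  Both one- and two-sided p-values are always populated.
    """

    u_statistic: float
    z_value: float
    p_two_sided: float
    p_one_sided_greater: float
    p_one_sided_less: float
    n_x: int
    n_y: int
    method: str  # "normal_approx" | "exact_permutation"

    def pvalue(self, alternative: str = "two-sided") -> float:
        if alternative == "two-sided":
            return self.p_two_sided
        if alternative == "greater":
            return self.p_one_sided_greater
        if alternative == "less":
            return self.p_one_sided_less
        raise ValueError(f"unknown alternative {alternative!r}")


@dataclass(frozen=True)
class ROCCurve:
    """Empirical ROC curve over a descending threshold sweep.

    thresholds[0] is a +inf sentinel giving the (0, 0) corner; subsequent
    thresholds are the unique observed scores in descending order, and the
    classification rule at threshold t is ``score >= t``.  Ties between
    positive and negative scores contribute half a pair to the trapezoidal
    area, so ``auc * n_pos * n_neg`` equals the rank-sum U statistic.
    """

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    n_pos: int
    n_neg: int


def _as_sample(a, name: str) -> np.ndarray:
    arr = np.asarray(a, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError(f"{name} sample is empty")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} sample contains non-finite values")
    return arr


def _u_statistic_from_ranks(ranks_x: np.ndarray, n1: int) -> float:
    return float(ranks_x.sum() - n1 * (n1 + 1) / 2.0)


def rank_sum_test(x, y, alternative: str = "two-sided", method: str = "auto") -> RankSumResult:
    """Mann-Whitney rank-sum test for two independent samples.

    Parameters
    ----------
    x, y : array-like
        Independent samples; the sign convention is "x greater".
    alternative : {"two-sided", "greater", "less"}
        Only affects :meth:`RankSumResult.pvalue`; all p-values are computed.
    method : {"auto", "exact", "approx"}
        "auto" enumerates all C(n1+n2, n1) splits when the combined sample
        has at most 20 observations or n1*n2 <= 400, provided the number of
        splits is tractable; otherwise it uses the tie-corrected normal
        approximation with a 0.5 continuity correction.
    """
    xa = _as_sample(x, "x")
    ya = _as_sample(y, "y")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    n1, n2 = xa.size, ya.size
    n = n1 + n2
    pooled = np.concatenate([xa, ya])
    ranks = rankdata(pooled)  # midranks
    u = _u_statistic_from_ranks(ranks[:n1], n1)
    mu = n1 * n2 / 2.0

    # tie-corrected variance of U under the null
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts.astype(float) ** 3 - counts))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1))) if n > 1 else 0.0
    sd = math.sqrt(var) if var > 0 else 0.0
    z = (u - mu) / sd if sd > 0 else 0.0

    n_splits = math.comb(n, n1)
    small = (n <= 20) or (n1 * n2 <= 400)
    if method == "exact" and n_splits > MAX_EXACT_SPLITS:
        raise ValueError(f"exact enumeration infeasible: C({n},{n1}) = {n_splits} splits")
    use_exact = method == "exact" or (method == "auto" and small and n_splits <= MAX_EXACT_SPLITS)

    if use_exact:
        offset = n1 * (n1 + 1) / 2.0
        u_all = np.fromiter(
            (ranks[list(idx)].sum() - offset for idx in itertools.combinations(range(n), n1)),
            dtype=float,
            count=n_splits,
        )
        eps = 1e-9
        p_greater = float(np.mean(u_all >= u - eps))
        p_less = float(np.mean(u_all <= u + eps))
        p_two = float(np.mean(np.abs(u_all - mu) >= abs(u - mu) - eps))
        return RankSumResult(
            u, z, min(1.0, p_two), min(1.0, p_greater), min(1.0, p_less), n1, n2, "exact_permutation"
        )

    if sd == 0.0:  # all observations tied: no evidence either way
        return RankSumResult(u, 0.0, 1.0, 0.5, 0.5, n1, n2, "normal_approx")

    # a p that underflows the normal tail is a floor, never a literal zero
    floor = 1e-300

    def _clamp(p: float) -> float:
        return min(1.0, max(p, floor))

    p_greater = float(norm.sf((u - mu - 0.5) / sd))
    p_less = float(norm.sf((mu - u - 0.5) / sd))
    p_two = float(2.0 * norm.sf(max(abs(u - mu) - 0.5, 0.0) / sd))
    return RankSumResult(
        u, z, _clamp(p_two), _clamp(p_greater), _clamp(p_less), n1, n2, "normal_approx"
    )


def roc_curve(scores_positive, scores_negative) -> ROCCurve:
    """Empirical ROC curve from positive- and negative-class scores.

    The sweep visits +inf then every unique observed score descending, so the
    curve always passes through (0, 0) and (1, 1).  AUC is the trapezoidal
    area, identical to the normalized rank-sum U statistic.
    """
    pos = _as_sample(scores_positive, "positive")
    neg = _as_sample(scores_negative, "negative")
    uniq = np.unique(np.concatenate([pos, neg]))[::-1]  # descending
    thresholds = np.concatenate([[np.inf], uniq])

    pos_sorted = np.sort(pos)
    neg_sorted = np.sort(neg)
    # score >= t  <=>  index past the left insertion point of t
    tpr = 1.0 - np.searchsorted(pos_sorted, thresholds, side="left") / pos.size
    fpr = 1.0 - np.searchsorted(neg_sorted, thresholds, side="left") / neg.size
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(thresholds, fpr, tpr, auc, pos.size, neg.size)


def optimal_threshold(curve: ROCCurve) -> tuple[float, float, float]:
    """Youden operating point: the threshold maximizing J = TPR - FPR.

    Ties are broken toward the higher threshold (fewer positive calls).  The
    +inf sentinel is not a candidate.  Returns (threshold, sensitivity,
    specificity).
    """
    finite = np.isfinite(curve.thresholds)
    if finite.sum() < 2:
        raise ValueError("degenerate ROC curve: fewer than two candidate thresholds")
    j = curve.tpr - curve.fpr
    j = np.where(finite, j, -np.inf)
    best = int(np.argmax(j))  # first maximum = highest threshold (descending sweep)
    return (
        float(curve.thresholds[best]),
        float(curve.tpr[best]),
        float(1.0 - curve.fpr[best]),
    )
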