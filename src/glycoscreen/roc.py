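"""Empirical ROC curves, AUC two ways, DeLong comparison, optimal cutoffs.

The curve is built over every distinct observed score with ``>=``
positivity, so one operating point per threshold plus the (0,0)/(1,1)
anchors.  AUC is available as the trapezoidal integral of the curve and,
equivalently, as the rank statistic: the probability that a random diseased
subject outscores a random non-diseased one, ties counting one half.  The
two agree to numerical precision and the rank form admits per-subject
weights.

Correlated AUCs (two scores on the same subjects) are compared with
DeLong's nonparametric test computed from midrank placement values, giving
a 1-df chi-square statistic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats


class DegenerateComparisonError(ValueError):
    """The AUC comparison is undefined (single class or zero variance)."""


@dataclass(frozen=True)
class RocCurve:
    """Operating points sorted by threshold descending, with anchors.

    ``thresholds[0] = +inf`` anchors (fpr, tpr) = (0, 0) and
    ``thresholds[-1] = -inf`` anchors (1, 1); interior thresholds are the
    distinct observed scores.  ``tpr`` is sensitivity and ``fpr`` is
    1 − specificity, both as proportions.
    """

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray

    def __post_init__(self) -> None:
        t, se, fp = map(np.asarray, (self.thresholds, self.tpr, self.fpr))
        if not (t.shape == se.shape == fp.shape) or t.ndim != 1 or t.size < 2:
            raise ValueError("curve arrays must be equal-length 1-D with >= 2 points")
        if (np.diff(t) > 0).any():
            raise ValueError("thresholds must be non-increasing")
        if (np.diff(se) < -1e-12).any() or (np.diff(fp) < -1e-12).any():
            raise ValueError("TPR and FPR must be non-decreasing along the curve")

    def interior(self) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(thresholds, tpr, fpr) at the observed (finite) operating points."""
        m = np.isfinite(self.thresholds)
        return self.thresholds[m], self.tpr[m], self.fpr[m]


@dataclass(frozen=True)
class AucComparison:
    """Result of a paired DeLong test between two correlated AUCs."""

    auc_a: float
    auc_b: float
    chi_square: float
    p_value: float
    variance: float


def empirical_roc(
    scores: Sequence[float],
    disease: Sequence[bool],
    weights: Optional[Sequence[float]] = None,
) -> RocCurve:
    """Weighted empirical ROC over all distinct score thresholds."""
    s = np.asarray(scores, dtype=float)
    d = np.asarray(disease, dtype=bool)
    if s.shape != d.shape:
        raise ValueError("scores and disease labels must have equal length")
    if weights is None:
        w = np.ones_like(s)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != s.shape:
            raise ValueError("weights must match scores in length")
        if (w <= 0).any():
            raise ValueError("weights must be positive")
    if not d.any() or d.all():
        raise DegenerateComparisonError("single-class input: ROC undefined")

    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    pos_w = np.where(d[order], w[order], 0.0).cumsum()
    neg_w = np.where(d[order], 0.0, w[order]).cumsum()
    # last index of each tie block = cumulative weight at "score >= threshold"
    is_block_end = np.r_[s_sorted[1:] != s_sorted[:-1], True]
    thr = s_sorted[is_block_end]
    tpr = pos_w[is_block_end] / pos_w[-1]
    fpr = neg_w[is_block_end] / neg_w[-1]
    thresholds = np.r_[np.inf, thr, -np.inf]
    return RocCurve(
        thresholds=thresholds,
        tpr=np.r_[0.0, tpr, 1.0],
        fpr=np.r_[0.0, fpr, 1.0],
    )


def auc_trapezoidal(curve: RocCurve) -> float:
    """Area under the ROC curve by the trapezoidal rule."""
    return float(np.trapezoid(curve.tpr, curve.fpr))


def auc_rank(
    scores: Sequence[float],
    disease: Sequence[bool],
    weights: Optional[Sequence[float]] = None,
) -> float:
    """Rank (Mann–Whitney) AUC with ties counting one half; weights allowed.

    With weights this is Σᵢⱼ uᵢvⱼ·ψ(xᵢ, yⱼ) / (ΣuᵢΣvⱼ) over diseased scores
    x with weights u and non-diseased scores y with weights v, computed in
    O(n log n) by a sweep over sorted scores.
    """
    s = np.asarray(scores, dtype=float)
    d = np.asarray(disease, dtype=bool)
    if s.shape != d.shape:
        raise ValueError("scores and disease labels must have equal length")
    if weights is None:
        w = np.ones_like(s)
    else:
        w = np.asarray(weights, dtype=float)
        if (w <= 0).any():
            raise ValueError("weights must be positive")
    if not d.any() or d.all():
        raise DegenerateComparisonError("single-class input: AUC undefined")

    order = np.argsort(s, kind="stable")
    s_sorted, d_sorted, w_sorted = s[order], d[order], w[order]
    pos_w = np.where(d_sorted, w_sorted, 0.0)
    neg_w = np.where(d_sorted, 0.0, w_sorted)
    block_end = np.r_[s_sorted[1:] != s_sorted[:-1], True]
    # per tie-block sums of diseased / non-diseased weight
    idx = np.flatnonzero(block_end)
    pos_block = np.add.reduceat(pos_w, np.r_[0, idx[:-1] + 1])
    neg_block = np.add.reduceat(neg_w, np.r_[0, idx[:-1] + 1])
    neg_below = np.r_[0.0, neg_block.cumsum()[:-1]]
    num = float((pos_block * (neg_below + 0.5 * neg_block)).sum())
    return num / (pos_w.sum() * neg_w.sum())


def _placements(scores: np.ndarray, disease: np.ndarray) -> Tuple[np.ndarray, np.ndarray, float]:
    """DeLong placement values via midranks.

    Returns (v01 per diseased subject, v10 per non-diseased subject, AUC):
    v01ᵢ is the fraction of non-diseased subjects the i-th diseased subject
    outscores (ties half), and symmetrically for v10.
    """
    x = scores[disease]
    y = scores[~disease]
    m, n = len(x), len(y)
    tz = stats.rankdata(np.r_[x, y])
    tx = stats.rankdata(x)
    ty = stats.rankdata(y)
    v01 = (tz[:m] - tx) / n
    v10 = 1.0 - (tz[m:] - ty) / m
    auc = (tz[:m].sum() - m * (m + 1) / 2) / (m * n)
    return v01, v10, float(auc)


def delong_auc_variance(scores: Sequence[float], disease: Sequence[bool]) -> float:
    """DeLong variance estimate of a single empirical AUC (unit weights)."""
    s = np.asarray(scores, dtype=float)
    d = np.asarray(disease, dtype=bool)
    if not d.any() or d.all():
        raise DegenerateComparisonError("single-class input")
    v01, v10, _ = _placements(s, d)
    m, n = len(v01), len(v10)
    if m < 2 or n < 2:
        raise DegenerateComparisonError("need >= 2 subjects per class for a variance")
    return float(np.var(v01, ddof=1) / m + np.var(v10, ddof=1) / n)


def delong_compare(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    disease: Sequence[bool],
) -> AucComparison:
    """DeLong's test for the difference of two correlated AUCs.

    Both scores are measured on the same subjects (unit weights).  The
    statistic (AUC_a − AUC_b)² / Var(AUC_a − AUC_b) is referred to a 1-df
    chi-square.  Identical AUCs with zero estimated variance yield a null
    result (χ²=0, p=1); differing AUCs with zero variance are degenerate.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    d = np.asarray(disease, dtype=bool)
    if not (a.shape == b.shape == d.shape):
        raise ValueError("scores_a, scores_b and disease must have equal length")
    if not d.any() or d.all():
        raise DegenerateComparisonError("single-class input")
    v01_a, v10_a, auc_a = _placements(a, d)
    v01_b, v10_b, auc_b = _placements(b, d)
    m, n = len(v01_a), len(v10_a)
    if m < 2 or n < 2:
        raise DegenerateComparisonError("need >= 2 subjects per class")
    s10 = np.cov(np.stack([v01_a, v01_b]), ddof=1)
    s01 = np.cov(np.stack([v10_a, v10_b]), ddof=1)
    cov = s10 / m + s01 / n
    var_diff = float(cov[0, 0] + cov[1, 1] - 2 * cov[0, 1])
    diff = auc_a - auc_b
    if var_diff <= 0:
        if np.isclose(diff, 0.0):
            return AucComparison(auc_a, auc_b, 0.0, 1.0, 0.0)
        raise DegenerateComparisonError(
            "zero variance estimate with unequal AUCs: comparison undefined"
        )
    chi2 = diff**2 / var_diff
    p = float(stats.chi2.sf(chi2, df=1))
    return AucComparison(auc_a, auc_b, float(chi2), p, var_diff)


def optimal_cutoff_by_distance(curve: RocCurve) -> float:
    """Threshold minimising the distance to the perfect (0, 1) ROC corner.

    Ties break toward the higher threshold (fewer screen-positives).
    """
    thr, tpr, fpr = curve.interior()
    if thr.size == 0:
        raise ValueError("curve has no interior operating points")
    dist = np.hypot(1.0 - tpr, fpr)
    # thresholds are sorted descending, so the first minimum is the highest
    return float(thr[int(np.argmin(dist))])


def curve_to_table(curve: RocCurve):
    """ROC curve as a DataFrame (threshold, sensitivity, specificity in %)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "threshold": curve.thresholds,
            "sensitivity": 100.0 * curve.tpr,
            "specificity": 100.0 * (1.0 - curve.fpr),
        }
    )


def plot_roc(curves: dict, path: Optional[str] = None, title: str = "ROC"):
    """Plot named ROC curves (requires the optional matplotlib extra)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for name, curve in curves.items():
        ax.plot(curve.fpr, curve.tpr, label=f"{name} (AUC={auc_trapezoidal(curve):.2f})")
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.set_title(title)
    ax.legend(loc="lower right")
    if path:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
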