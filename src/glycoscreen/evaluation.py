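"""Binary screening tests and diagnostic-accuracy metrics.

An index test is a :class:`BinaryTestSpec` tree: leaves compare the FINDRISC
total or HbA1c against a cutoff with ``>=`` semantics; internal nodes
combine two tests in parallel ("simultaneous": positive on either) or in
series ("sequential": positive on both).  Metrics are computed against the
OGTT-based glycemic reference, optionally with survey weights, and include
the screening-table derived columns: the sensitivity+specificity sum, the
Euclidean distance from the ROC operating point to the perfect corner, and
the screened-positive population fraction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from glycoscreen.findrisc import score_cohort
from glycoscreen.glycemia import (
    GlycemicClass,
    PREDIABETES_CLASSES,
    classify_cohort,
)
from glycoscreen.records import ParticipantRecord

LEAF_KINDS = ("findrisc_ge", "hba1c_ge")
COMBINATION_KINDS = ("parallel_or", "serial_and")

#: Outcomes evaluate_model understands; pre-diabetes and its subtypes drop
#: diabetic subjects from the evaluation set first.
TARGETS = ("diabetes", "prediabetes", "iIFG", "iIGT")


class UndefinedMetricError(ValueError):
    """A metric's denominator is empty (e.g. no diseased subjects)."""


@dataclass(frozen=True)
class BinaryTestSpec:
    """A leaf cutoff test or a two-operand combination of tests."""

    kind: str
    threshold: Optional[float] = None
    operands: Optional[Tuple["BinaryTestSpec", "BinaryTestSpec"]] = None

    def __post_init__(self) -> None:
        if self.kind in LEAF_KINDS:
            if self.threshold is None or self.operands is not None:
                raise ValueError(f"leaf test {self.kind!r} needs exactly one threshold")
        elif self.kind in COMBINATION_KINDS:
            if self.operands is None or len(self.operands) != 2 or self.threshold is not None:
                raise ValueError(f"combination {self.kind!r} needs exactly two operands")
        else:
            raise ValueError(f"unknown test kind {self.kind!r}")

    def describe(self) -> str:
        if self.kind == "findrisc_ge":
            return f"FINDRISC>={self.threshold:g}"
        if self.kind == "hba1c_ge":
            return f"HbA1c>={self.threshold:g}"
        joiner = " OR " if self.kind == "parallel_or" else " AND "
        return "(" + joiner.join(op.describe() for op in self.operands) + ")"


def findrisc_ge(threshold: float) -> BinaryTestSpec:
    return BinaryTestSpec("findrisc_ge", threshold=threshold)


def hba1c_ge(threshold: float) -> BinaryTestSpec:
    return BinaryTestSpec("hba1c_ge", threshold=threshold)


def parallel_or(a: BinaryTestSpec, b: BinaryTestSpec) -> BinaryTestSpec:
    """Simultaneous testing: positive if positive on either component."""
    return BinaryTestSpec("parallel_or", operands=(a, b))


def serial_and(a: BinaryTestSpec, b: BinaryTestSpec) -> BinaryTestSpec:
    """Sequential testing: positive only if positive on both components."""
    return BinaryTestSpec("serial_and", operands=(a, b))


@dataclass(frozen=True)
class ConfusionCounts:
    """2×2 table against the reference; weighted counts are permitted."""

    tp: float
    fp: float
    tn: float
    fn: float

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def total(self) -> float:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class DiagnosticMetrics:
    """Accuracy statistics in percent, plus the derived screening columns.

    ``ppv``/``npv`` are the crude (within-sample) predictive values; when
    a reference prevalence is supplied to the sweep helpers the
    prevalence-adjusted values are reported alongside.  ``ppv`` is NaN when
    nobody tests positive and ``npv`` is NaN when nobody tests negative.
    """

    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    sum: float
    roc_distance: float
    fraction_positive: float


def apply_test(
    spec: BinaryTestSpec, record: ParticipantRecord, findrisc_total: int
) -> bool:
    """Evaluate one test tree on one subject."""
    if spec.kind == "findrisc_ge":
        return findrisc_total >= spec.threshold
    if spec.kind == "hba1c_ge":
        if record.hba1c is None:
            raise ValueError("hba1c is missing; cannot apply HbA1c test")
        return record.hba1c >= spec.threshold
    a = apply_test(spec.operands[0], record, findrisc_total)
    b = apply_test(spec.operands[1], record, findrisc_total)
    return (a or b) if spec.kind == "parallel_or" else (a and b)


def apply_test_cohort(
    spec: BinaryTestSpec, df: pd.DataFrame, findrisc_totals: pd.Series
) -> pd.Series:
    """Vectorised test evaluation over a cohort frame."""
    if spec.kind == "findrisc_ge":
        return findrisc_totals >= spec.threshold
    if spec.kind == "hba1c_ge":
        if df["hba1c"].isna().any():
            bad = df.index[df["hba1c"].isna()].tolist()[:10]
            raise ValueError(f"hba1c missing; run exclusions first (rows {bad})")
        return df["hba1c"] >= spec.threshold
    a = apply_test_cohort(spec.operands[0], df, findrisc_totals)
    b = apply_test_cohort(spec.operands[1], df, findrisc_totals)
    return (a | b) if spec.kind == "parallel_or" else (a & b)


def build_confusion(
    test_results: Sequence[bool],
    disease: Sequence[bool],
    weights: Optional[Sequence[float]] = None,
) -> ConfusionCounts:
    """Weighted 2×2 tally of test positivity against disease status."""
    t = np.asarray(test_results, dtype=bool)
    d = np.asarray(disease, dtype=bool)
    if t.shape != d.shape:
        raise ValueError(f"length mismatch: {t.shape} test results vs {d.shape} labels")
    if weights is None:
        w = np.ones(t.shape)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != t.shape:
            raise ValueError(f"length mismatch: {w.shape} weights vs {t.shape} results")
        if (w <= 0).any():
            raise ValueError("weights must be positive")
    return ConfusionCounts(
        tp=float(w[t & d].sum()),
        fp=float(w[t & ~d].sum()),
        tn=float(w[~t & ~d].sum()),
        fn=float(w[~t & d].sum()),
    )


def roc_distance(sensitivity: float, specificity: float) -> float:
    """Distance from the (sensitivity, specificity) point to the perfect
    corner: sqrt((1-se)² + (1-sp)²), with se/sp given in percent."""
    for name, v in (("sensitivity", sensitivity), ("specificity", specificity)):
        if not 0 <= v <= 100:
            raise ValueError(f"{name} must be in [0, 100], got {v}")
    se = sensitivity / 100.0
    sp = specificity / 100.0
    return float(np.hypot(1.0 - se, 1.0 - sp))


def metrics_from_confusion(c: ConfusionCounts) -> DiagnosticMetrics:
    """Sensitivity/specificity/PVs (percent) and derived columns from a 2×2."""
    if c.tp + c.fn <= 0:
        raise UndefinedMetricError("no diseased subjects: sensitivity undefined")
    if c.tn + c.fp <= 0:
        raise UndefinedMetricError("no non-diseased subjects: specificity undefined")
    se = 100.0 * c.tp / (c.tp + c.fn)
    sp = 100.0 * c.tn / (c.tn + c.fp)
    ppv = 100.0 * c.tp / (c.tp + c.fp) if c.tp + c.fp > 0 else float("nan")
    npv = 100.0 * c.tn / (c.tn + c.fn) if c.tn + c.fn > 0 else float("nan")
    return DiagnosticMetrics(
        sensitivity=se,
        specificity=sp,
        ppv=ppv,
        npv=npv,
        sum=se + sp,
        roc_distance=roc_distance(se, sp),
        fraction_positive=100.0 * (c.tp + c.fp) / c.total,
    )


def prevalence_adjusted_predictive_values(
    sensitivity: float, specificity: float, prevalence: float
) -> Tuple[float, float]:
    """PPV and NPV (percent) at an external prevalence via Bayes' rule.

    se/sp in percent; prevalence as a proportion in (0, 1).
    """
    if not 0 < prevalence < 1:
        raise ValueError(f"prevalence must be in (0, 1), got {prevalence}")
    se = sensitivity / 100.0
    sp = specificity / 100.0
    p = prevalence
    pos = se * p + (1 - sp) * (1 - p)
    neg = (1 - se) * p + sp * (1 - p)
    if pos <= 0 or neg <= 0:
        raise UndefinedMetricError("degenerate test: everyone on one side")
    return 100.0 * se * p / pos, 100.0 * sp * (1 - p) / neg


def population_positive_fraction(
    sensitivity: float, specificity: float, prevalence: float
) -> float:
    """Percent of the screened population testing positive at the given
    operating point and prevalence."""
    if not 0 < prevalence < 1:
        raise ValueError(f"prevalence must be in (0, 1), got {prevalence}")
    se = sensitivity / 100.0
    sp = specificity / 100.0
    return 100.0 * (se * prevalence + (1 - sp) * (1 - prevalence))


def _target_masks(classes: pd.Series, target: str) -> Tuple[pd.Series, pd.Series]:
    """(evaluation-set mask, disease mask) for a screening outcome.

    Pre-diabetes outcomes (including the isolated subtypes) exclude
    diabetic subjects from the evaluation set before metrics are formed.
    """
    if target == "diabetes":
        keep = pd.Series(True, index=classes.index)
        disease = classes == GlycemicClass.DM
    elif target == "prediabetes":
        keep = classes != GlycemicClass.DM
        disease = classes.isin(PREDIABETES_CLASSES)
    elif target == "iIFG":
        keep = classes != GlycemicClass.DM
        disease = classes == GlycemicClass.iIFG
    elif target == "iIGT":
        keep = classes != GlycemicClass.DM
        disease = classes == GlycemicClass.iIGT
    else:
        raise ValueError(f"unknown target {target!r}; expected one of {TARGETS}")
    return keep, disease


def evaluate_model(
    df: pd.DataFrame,
    test: BinaryTestSpec,
    target: str = "diabetes",
    use_weights: bool = True,
    min_age: Optional[float] = None,
    findrisc_totals: Optional[pd.Series] = None,
    classes: Optional[pd.Series] = None,
) -> DiagnosticMetrics:
    """Evaluate a screening test against the OGTT reference on a cohort.

    ``df`` must already have passed the exclusion cascade (no missing labs).
    FINDRISC totals and glycemic classes are computed on the fly unless
    supplied.  ``min_age`` restricts the evaluation set (e.g. 45 for the
    older-adult sensitivity analysis).
    """
    if findrisc_totals is None:
        findrisc_totals = score_cohort(df)
    if classes is None:
        classes = classify_cohort(df)
    keep, disease = _target_masks(classes, target)
    if min_age is not None:
        keep = keep & (df["age"] >= min_age)
    sub = df[keep]
    if sub.empty:
        raise UndefinedMetricError(f"no subjects left for target {target!r}")
    results = apply_test_cohort(test, sub, findrisc_totals[keep])
    weights = sub["survey_weight"] if use_weights else None
    c = build_confusion(results.to_numpy(), disease[keep].to_numpy(),
                        None if weights is None else weights.to_numpy())
    return metrics_from_confusion(c)
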