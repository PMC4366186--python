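"""End-to-end screening analysis: eligibility, scoring, sweep, models, ROC.

`run_full_analysis` reproduces the study's analysis structure on any
cohort frame: a descriptive summary by glycemic class, the FINDRISC cutoff
sweep for diabetes and pre-diabetes (diabetes excluded for the latter), the
three screening models (HbA1c alone, FINDRISC alone, their parallel
combination — plus the serial combination for contrast) for four outcomes,
ROC/AUC analysis with DeLong comparisons, and optionally the same model
block restricted to ages 45 and over.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from glycoscreen.evaluation import (
    DiagnosticMetrics,
    evaluate_model,
    findrisc_ge,
    hba1c_ge,
    parallel_or,
    population_positive_fraction,
    prevalence_adjusted_predictive_values,
    serial_and,
    _target_masks,
)
from glycoscreen.findrisc import score_cohort
from glycoscreen.glycemia import (
    HBA1C_DM,
    HBA1C_PREDM,
    apply_exclusions,
    classify_cohort,
)
from glycoscreen.roc import (
    auc_trapezoidal,
    delong_compare,
    empirical_roc,
    optimal_cutoff_by_distance,
)
from glycoscreen.simulate import CLASS_ORDER
from glycoscreen.weighting import weighted_prevalence

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnalysisConfig:
    """Knobs of the full analysis.

    ``prevalence_override`` replaces the weighted sample prevalence in the
    prevalence-adjusted predictive-value columns (e.g. 0.07 to use an
    externally reported undiagnosed-diabetes prevalence).
    """

    findrisc_cutoffs: Sequence[int] = tuple(range(5, 10))
    hba1c_cutoff_diabetes: float = HBA1C_DM
    hba1c_cutoff_prediabetes: float = HBA1C_PREDM
    findrisc_cutoff_combined: int = 9
    prevalence_override: Optional[float] = None
    use_weights: bool = True
    min_age: Optional[float] = None
    age45_sensitivity: bool = False

    def __post_init__(self) -> None:
        if not self.findrisc_cutoffs:
            raise ValueError("findrisc cutoff sweep must be non-empty")
        if any(not 0 <= c <= 26 for c in self.findrisc_cutoffs):
            raise ValueError("findrisc cutoffs must lie in [0, 26]")
        for v in (self.hba1c_cutoff_diabetes, self.hba1c_cutoff_prediabetes):
            if not 0 < v < 20:
                raise ValueError(f"implausible HbA1c cutoff {v}")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _metrics_row(m: DiagnosticMetrics) -> dict:
    return {
        "sensitivity": m.sensitivity,
        "specificity": m.specificity,
        "ppv": m.ppv,
        "npv": m.npv,
        "sum": m.sum,
        "roc_distance": m.roc_distance,
        "fraction_positive": m.fraction_positive,
    }


def _hba1c_cutoff_for(config: AnalysisConfig, target: str) -> float:
    return config.hba1c_cutoff_diabetes if target == "diabetes" else config.hba1c_cutoff_prediabetes


def descriptive_by_class(df: pd.DataFrame, classes: pd.Series, scores: pd.Series) -> pd.DataFrame:
    """Per-class counts, shares and mean (SD) of the analytes and score."""
    rows = []
    n_total = len(df)
    for cls in CLASS_ORDER:
        sel = classes == cls
        sub = df[sel]
        row = {
            "glycemic_class": cls.value,
            "n": int(sel.sum()),
            "pct": 100.0 * sel.sum() / n_total if n_total else np.nan,
        }
        for col in ("age", "waist", "fpg", "pg2h", "hba1c"):
            row[f"{col}_mean"] = sub[col].mean()
            row[f"{col}_sd"] = sub[col].std(ddof=1)
        row["findrisc_mean"] = scores[sel].mean()
        row["findrisc_sd"] = scores[sel].std(ddof=1)
        rows.append(row)
    return pd.DataFrame(rows)


def cutoff_sweep(
    df: pd.DataFrame,
    classes: pd.Series,
    scores: pd.Series,
    target: str,
    cutoffs: Sequence[int],
    use_weights: bool = True,
    prevalence: Optional[float] = None,
    min_age: Optional[float] = None,
) -> pd.DataFrame:
    """FINDRISC cutoff sweep in the shape of the study's screening table.

    ``ppv``/``npv`` are crude within-sample values; ``ppv_adjusted``/
    ``npv_adjusted`` and ``pct_population`` apply the Bayes formulas at the
    supplied (or weighted sample) prevalence.
    """
    if prevalence is None:
        keep, disease = _target_masks(classes, target)
        if min_age is not None:
            keep &= df["age"] >= min_age
        prevalence = weighted_prevalence(df[keep], disease[keep].to_numpy()).estimate
    rows = []
    for c in cutoffs:
        m = evaluate_model(
            df, findrisc_ge(c), target=target, use_weights=use_weights,
            min_age=min_age, findrisc_totals=scores, classes=classes,
        )
        ppv_adj, npv_adj = prevalence_adjusted_predictive_values(
            m.sensitivity, m.specificity, prevalence
        )
        rows.append(
            {
                "cutoff": c,
                **_metrics_row(m),
                "ppv_adjusted": ppv_adj,
                "npv_adjusted": npv_adj,
                "pct_population": population_positive_fraction(
                    m.sensitivity, m.specificity, prevalence
                ),
                "prevalence_used": prevalence,
            }
        )
    return pd.DataFrame(rows)


def model_comparison(
    df: pd.DataFrame,
    classes: pd.Series,
    scores: pd.Series,
    config: AnalysisConfig,
    min_age: Optional[float] = None,
) -> pd.DataFrame:
    """HbA1c alone vs FINDRISC alone vs parallel/serial combinations."""
    rows = []
    for target in ("diabetes", "prediabetes", "iIFG", "iIGT"):
        h = hba1c_ge(_hba1c_cutoff_for(config, target))
        f = findrisc_ge(config.findrisc_cutoff_combined)
        for label, spec in (
            ("hba1c_alone", h),
            ("findrisc_alone", f),
            ("simultaneous_or", parallel_or(f, h)),
            ("sequential_and", serial_and(f, h)),
        ):
            m = evaluate_model(
                df, spec, target=target, use_weights=config.use_weights,
                min_age=min_age, findrisc_totals=scores, classes=classes,
            )
            rows.append(
                {"target": target, "model": label, "test": spec.describe(), **_metrics_row(m)}
            )
    return pd.DataFrame(rows)


def roc_block(
    df: pd.DataFrame,
    classes: pd.Series,
    scores: pd.Series,
    config: AnalysisConfig,
    min_age: Optional[float] = None,
) -> dict:
    """ROC curves and AUCs for FINDRISC and HbA1c, with DeLong comparison.

    AUC point estimates honour ``use_weights``; the DeLong comparison is
    defined for unit weights and is always computed unweighted.
    """
    out = {}
    for target in ("diabetes", "prediabetes"):
        keep, disease = _target_masks(classes, target)
        if min_age is not None:
            keep &= df["age"] >= min_age
        sub = df[keep]
        d = disease[keep].to_numpy()
        w = sub["survey_weight"].to_numpy() if config.use_weights else None
        fr = scores[keep].to_numpy(float)
        hb = sub["hba1c"].to_numpy(float)
        curve_f = empirical_roc(fr, d, w)
        curve_h = empirical_roc(hb, d, w)
        cmp_res = delong_compare(fr, hb, d)
        out[target] = {
            "auc_findrisc": auc_trapezoidal(curve_f),
            "auc_hba1c": auc_trapezoidal(curve_h),
            "delong_chi_square": cmp_res.chi_square,
            "delong_p_value": cmp_res.p_value,
            "optimal_findrisc_cutoff": optimal_cutoff_by_distance(curve_f),
            "curve_findrisc": pd.DataFrame(
                {"threshold": curve_f.thresholds, "tpr": curve_f.tpr, "fpr": curve_f.fpr}
            ),
            "curve_hba1c": pd.DataFrame(
                {"threshold": curve_h.thresholds, "tpr": curve_h.tpr, "fpr": curve_h.fpr}
            ),
        }
    return out


def run_full_analysis(cohort: pd.DataFrame, config: AnalysisConfig = AnalysisConfig()) -> dict:
    """Run every stage on a raw cohort frame and return the report bundle."""
    from glycoscreen import __version__
    from glycoscreen.records import validate_cohort

    validate_cohort(cohort)
    retained, tally = apply_exclusions(cohort)
    if retained.empty:
        raise ValueError("no records survive the eligibility cascade")
    scores = score_cohort(retained)
    classes = classify_cohort(retained)
    min_age = config.min_age
    bundle = {
        "exclusions": {"input": len(cohort), "retained": len(retained), **tally},
        "descriptive": descriptive_by_class(retained, classes, scores),
        "sweep_diabetes": cutoff_sweep(
            retained, classes, scores, "diabetes", config.findrisc_cutoffs,
            config.use_weights, config.prevalence_override, min_age,
        ),
        "sweep_prediabetes": cutoff_sweep(
            retained, classes, scores, "prediabetes", config.findrisc_cutoffs,
            config.use_weights, config.prevalence_override, min_age,
        ),
        "models": model_comparison(retained, classes, scores, config, min_age),
        "roc": roc_block(retained, classes, scores, config, min_age),
        "meta": {"version": __version__, "config": asdict(config), "config_hash": config.config_hash()},
    }
    if config.age45_sensitivity:
        bundle["age45_models"] = model_comparison(retained, classes, scores, config, min_age=45.0)
    logger.info("full analysis complete: %d retained, config %s", len(retained), config.config_hash())
    return bundle
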