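"""Survey-weight helpers: weighted prevalence and multi-cycle weight scaling.

Estimation only — design-based variance (strata/PSU linearisation,
replicate weights) is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Union

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class WeightedEstimate:
    """A weighted proportion (or mean) and Kish's effective sample size."""

    estimate: float
    effective_n: float


def weighted_prevalence(
    df: pd.DataFrame,
    predicate: Union[Callable[[pd.DataFrame], pd.Series], pd.Series, np.ndarray],
    weight_col: str = "survey_weight",
) -> WeightedEstimate:
    """Weighted fraction of subjects satisfying a predicate.

    ``predicate`` is a boolean mask or a callable mapping the frame to one.
    The effective n is (Σw)²/Σw², which never exceeds the raw count.
    """
    if df.empty:
        raise ValueError("empty cohort: prevalence undefined")
    mask = predicate(df) if callable(predicate) else predicate
    mask = np.asarray(mask, dtype=bool)
    w = df[weight_col].to_numpy(float)
    if (w <= 0).any():
        raise ValueError("survey weights must be positive")
    if mask.shape != w.shape:
        raise ValueError("predicate mask length must match the cohort")
    return WeightedEstimate(
        estimate=float(w[mask].sum() / w.sum()),
        effective_n=float(w.sum() ** 2 / (w**2).sum()),
    )


def weighted_mean(values: np.ndarray, weights: np.ndarray) -> float:
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.size == 0:
        raise ValueError("empty input: mean undefined")
    return float((v * w).sum() / w.sum())


def normalize_multicycle_weights(
    df: pd.DataFrame, n_cycles: int, weight_col: str = "survey_weight"
) -> pd.DataFrame:
    """Scale per-cycle weights for a cohort pooled over survey cycles.

    Each weight is divided by the number of pooled cycles so the pooled
    weights still sum to one population total; within-cycle relative
    weights are unchanged.  Returns a copy.
    """
    if n_cycles <= 0:
        raise ValueError(f"n_cycles must be positive, got {n_cycles}")
    out = df.copy()
    out[weight_col] = out[weight_col] / n_cycles
    return out
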