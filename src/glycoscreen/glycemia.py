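"""OGTT-based glycemic classification and the study exclusion cascade.

Participants are placed into five mutually exclusive classes from fasting
plasma glucose (FPG) and 2-h post-load plasma glucose (2-h PG), both in
mg/dL, per ADA criteria:

* ``DM``       — undiagnosed diabetes: FPG ≥ 126 or 2-h PG ≥ 200
* ``IFG_IGT``  — FPG in [100, 126) and 2-h PG in [140, 200)
* ``iIFG``     — isolated impaired fasting glucose: FPG in [100, 126), 2-h PG < 140
* ``iIGT``     — isolated impaired glucose tolerance: FPG < 100, 2-h PG in [140, 200)
* ``NGT``      — normal glucose tolerance: FPG < 100 and 2-h PG < 140

The pre-diabetes bands are half-open against the diabetes thresholds so the
five classes are exhaustive for any pair of positive glucose values.
"""

from __future__ import annotations

import enum
import logging
from typing import Optional, Tuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

FPG_IFG = 100.0
FPG_DM = 126.0
PG2H_IGT = 140.0
PG2H_DM = 200.0

HBA1C_DM = 6.5   # % — HbA1c screening cutoff for diabetes
HBA1C_PREDM = 5.7  # % — HbA1c screening cutoff for pre-diabetes


class GlycemicClass(str, enum.Enum):
    NGT = "NGT"
    iIFG = "iIFG"
    iIGT = "iIGT"
    IFG_IGT = "IFG_IGT"
    DM = "DM"


PREDIABETES_CLASSES = (GlycemicClass.iIFG, GlycemicClass.iIGT, GlycemicClass.IFG_IGT)

#: Ordered names of the sequential exclusion steps.
EXCLUSION_STEPS = (
    "age_lt_20",
    "fasting_out_of_range",
    "missing_hba1c",
    "missing_fpg",
    "missing_pg2h",
    "self_reported_diabetes",
)


def classify_glycemic(fpg: Optional[float], pg2h: Optional[float]) -> GlycemicClass:
    """Classify one (FPG, 2-h PG) pair into the five-class scheme."""
    if fpg is None or (isinstance(fpg, float) and np.isnan(fpg)):
        raise ValueError("fpg is missing; cannot classify")
    if pg2h is None or (isinstance(pg2h, float) and np.isnan(pg2h)):
        raise ValueError("pg2h is missing; cannot classify")
    if not fpg > 0:
        raise ValueError(f"fpg must be > 0, got {fpg}")
    if not pg2h > 0:
        raise ValueError(f"pg2h must be > 0, got {pg2h}")
    if fpg >= FPG_DM or pg2h >= PG2H_DM:
        return GlycemicClass.DM
    ifg = fpg >= FPG_IFG
    igt = pg2h >= PG2H_IGT
    if ifg and igt:
        return GlycemicClass.IFG_IGT
    if ifg:
        return GlycemicClass.iIFG
    if igt:
        return GlycemicClass.iIGT
    return GlycemicClass.NGT


def classify_cohort(df: pd.DataFrame) -> pd.Series:
    """Vectorised classification of a cohort frame (requires fpg/pg2h present)."""
    fpg = df["fpg"].to_numpy(float)
    pg2h = df["pg2h"].to_numpy(float)
    if np.isnan(fpg).any() or np.isnan(pg2h).any():
        bad = df.index[np.isnan(fpg) | np.isnan(pg2h)].tolist()[:10]
        raise ValueError(f"missing glucose values; run exclusions first (rows {bad})")
    dm = (fpg >= FPG_DM) | (pg2h >= PG2H_DM)
    ifg = (fpg >= FPG_IFG) & ~dm
    igt = (pg2h >= PG2H_IGT) & ~dm
    out = np.empty(len(df), dtype=object)
    out[:] = GlycemicClass.NGT
    out[ifg & ~igt] = GlycemicClass.iIFG
    out[igt & ~ifg] = GlycemicClass.iIGT
    out[ifg & igt] = GlycemicClass.IFG_IGT
    out[dm] = GlycemicClass.DM
    return pd.Series(out, index=df.index, name="glycemic_class")


def apply_exclusions(df: pd.DataFrame) -> Tuple[pd.DataFrame, dict]:
    """Apply the sequential study-eligibility cascade to a cohort frame.

    Steps, in order: (1) age < 20; (2) fasting shorter than 9 h or 24 h and
    longer; (3) missing HbA1c; (4) missing FPG; (5) missing 2-h PG;
    (6) self-reported diabetes.  A record failing several criteria is
    counted once, at the first step it fails.  Returns the retained frame
    and an ordered ``{step: count}`` tally; the retained count plus the
    tally total equals the input size.
    """
    tally = {step: 0 for step in EXCLUSION_STEPS}
    if df.empty:
        return df.copy(), tally
    masks = {
        "age_lt_20": df["age"] < 20,
        "fasting_out_of_range": (df["fasting_hours"] < 9) | (df["fasting_hours"] >= 24),
        "missing_hba1c": df["hba1c"].isna(),
        "missing_fpg": df["fpg"].isna(),
        "missing_pg2h": df["pg2h"].isna(),
        "self_reported_diabetes": df["self_reported_diabetes"].astype(bool),
    }
    alive = pd.Series(True, index=df.index)
    for step in EXCLUSION_STEPS:
        hit = alive & masks[step]
        tally[step] = int(hit.sum())
        alive &= ~hit
    retained = df[alive].copy()
    logger.info(
        "exclusion cascade: %d in, %d retained, tally=%s", len(df), len(retained), tally
    )
    return retained, tally
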