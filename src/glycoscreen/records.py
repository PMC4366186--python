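"""Participant record schema shared by every stage of the pipeline.

A cohort is carried as a :class:`pandas.DataFrame` whose columns are the
fields of :class:`ParticipantRecord`; missing laboratory values are ``NaN``
in the frame and ``None`` on the dataclass.  The schema is this package's
own — it does not mirror raw NHANES variable names.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import Optional

import pandas as pd

SEXES = ("male", "female")
FAMILY_HISTORY_LEVELS = ("none", "second_degree", "first_degree")

#: Canonical cohort CSV column order.
COHORT_COLUMNS = [
    "id",
    "age",
    "sex",
    "height",
    "weight",
    "waist",
    "uses_antihypertensive_med",
    "history_high_glucose",
    "family_history",
    "pa_minutes_commute",
    "pa_minutes_recreation",
    "pa_minutes_work",
    "fruit_veg_daily",
    "fpg",
    "pg2h",
    "hba1c",
    "fasting_hours",
    "self_reported_diabetes",
    "survey_weight",
    "survey_cycle",
]

BOOL_COLUMNS = [
    "uses_antihypertensive_med",
    "history_high_glucose",
    "fruit_veg_daily",
    "self_reported_diabetes",
]

#: Laboratory columns where missingness is meaningful (never imputed).
LAB_COLUMNS = ["fpg", "pg2h", "hba1c"]


@dataclass
class ParticipantRecord:
    """One subject: questionnaire, anthropometric, glycemic and design fields.

    Glucose units are mg/dL, HbA1c is NGSP percent, anthropometry is metric.
    ``fpg``, ``pg2h`` and ``hba1c`` may be ``None`` (explicitly missing); no
    other field may be missing.
    """

    id: str
    age: float
    sex: str
    height: float
    weight: float
    waist: float
    uses_antihypertensive_med: bool
    history_high_glucose: bool
    family_history: str
    pa_minutes_commute: float
    pa_minutes_recreation: float
    pa_minutes_work: float
    fruit_veg_daily: bool
    fpg: Optional[float] = None
    pg2h: Optional[float] = None
    hba1c: Optional[float] = None
    fasting_hours: float = 12.0
    self_reported_diabetes: bool = False
    survey_weight: float = 1.0
    survey_cycle: int = 1

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.family_history not in FAMILY_HISTORY_LEVELS:
            raise ValueError(
                f"family_history must be one of {FAMILY_HISTORY_LEVELS}, "
                f"got {self.family_history!r}"
            )
        if self.age < 0:
            raise ValueError(f"age must be >= 0, got {self.age}")
        for name in ("height", "weight", "waist", "survey_weight"):
            v = getattr(self, name)
            if not v > 0:
                raise ValueError(f"{name} must be > 0, got {v}")
        for name in ("pa_minutes_commute", "pa_minutes_recreation", "pa_minutes_work"):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if self.fasting_hours < 0:
            raise ValueError(f"fasting_hours must be >= 0, got {self.fasting_hours}")
        for name in LAB_COLUMNS:
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValueError(f"{name} must be > 0 or missing, got {v}")
        if self.survey_cycle not in (1, 2, 3):
            raise ValueError(f"survey_cycle must be 1, 2 or 3, got {self.survey_cycle}")

    @classmethod
    def from_row(cls, row: pd.Series) -> "ParticipantRecord":
        """Build a record from one cohort-frame row; NaN labs become None."""
        kwargs = {}
        for f in fields(cls):
            v = row[f.name]
            if f.name in LAB_COLUMNS and (v is None or (isinstance(v, float) and math.isnan(v))):
                v = None
            elif f.name in BOOL_COLUMNS:
                v = bool(v)
            elif f.name == "survey_cycle":
                v = int(v)
            kwargs[f.name] = v
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def records_to_frame(records: list) -> pd.DataFrame:
    """Stack ParticipantRecords into the canonical cohort frame."""
    if not records:
        return pd.DataFrame(columns=COHORT_COLUMNS)
    df = pd.DataFrame([r.to_dict() for r in records])
    return df[COHORT_COLUMNS]


def validate_cohort(df: pd.DataFrame) -> None:
    """Validate a cohort frame; raise ValueError naming offending rows.

    Checks the column set, numeric ranges and categorical levels.  Lab
    columns may be NaN; everything else must be present on every row.
    """
    missing_cols = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"cohort is missing required columns: {missing_cols}")
    if df.empty:
        return
    problems = []

    def flag(mask: pd.Series, msg: str) -> None:
        if mask.any():
            rows = df.index[mask].tolist()[:10]
            problems.append(f"{msg} (rows {rows})")

    flag(df["age"].isna() | (df["age"] < 0), "age must be >= 0")
    flag(~df["sex"].isin(SEXES), f"sex must be one of {SEXES}")
    flag(~df["family_history"].isin(FAMILY_HISTORY_LEVELS),
         f"family_history must be one of {FAMILY_HISTORY_LEVELS}")
    for c in ("height", "weight", "waist", "survey_weight"):
        flag(df[c].isna() | (df[c] <= 0), f"{c} must be > 0")
    for c in ("pa_minutes_commute", "pa_minutes_recreation", "pa_minutes_work"):
        flag(df[c].isna() | (df[c] < 0), f"{c} must be >= 0")
    flag(df["fasting_hours"].isna() | (df["fasting_hours"] < 0),
         "fasting_hours must be >= 0")
    for c in LAB_COLUMNS:
        flag(df[c].notna() & (df[c] <= 0), f"{c} must be > 0 when present")
    flag(~df["survey_cycle"].isin((1, 2, 3)), "survey_cycle must be 1, 2 or 3")
    if problems:
        raise ValueError("invalid cohort: " + "; ".join(problems))
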