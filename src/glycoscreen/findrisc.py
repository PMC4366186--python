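"""FINDRISC (Finnish Diabetes Risk Score) item scoring.

The score sums eight questionnaire/anthropometry items — age, BMI, waist
circumference, daily physical activity, daily fruit/vegetable/berry intake,
antihypertensive medication use, history of high blood glucose and family
history of diabetes — to a total between 0 and 26.  Point values follow the
original published instrument:

====================  =========================================  ======
item                  categories                                 points
====================  =========================================  ======
age (years)           <45 / 45–54 / 55–64 / ≥65                  0/2/3/4
BMI (kg/m²)           <25 / 25–30 / >30                          0/1/3
waist (cm), male      <94 / 94–102 / >102                        0/3/4
waist (cm), female    <80 / 80–88 / >88                          0/3/4
physical activity     ≥30 min/day / <30 min/day                  0/2
fruit & vegetables    daily / not daily                          0/1
BP medication         no / yes                                   0/2
high glucose history  no / yes                                   0/5
family history        none / second-degree / first-degree        0/3/5
====================  =========================================  ======

Boundaries are closed on the lower-risk side: BMI exactly 25 scores 1, a
male waist of exactly 94 cm scores 3, age exactly 45 scores 2, and exactly
30 min/day of activity scores 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
import numpy as np
import pandas as pd

from glycoscreen.records import ParticipantRecord

#: Allowed point values per item, in a fixed item order.  The cartesian
#: product of these sets (1728 combinations) spans every attainable
#: component profile; totals range over 0..26.
ITEM_POINT_SETS = {
    "age_pts": (0, 2, 3, 4),
    "bmi_pts": (0, 1, 3),
    "waist_pts": (0, 3, 4),
    "pa_pts": (0, 2),
    "fruitveg_pts": (0, 1),
    "med_pts": (0, 2),
    "glucose_hist_pts": (0, 5),
    "family_pts": (0, 3, 5),
}

MAX_TOTAL = 26


class MissingItemError(ValueError):
    """An item required for FINDRISC scoring is absent, named in the message."""


@dataclass(frozen=True)
class FindriscComponents:
    """The eight FINDRISC item sub-scores and their total."""

    age_pts: int
    bmi_pts: int
    waist_pts: int
    pa_pts: int
    fruitveg_pts: int
    med_pts: int
    glucose_hist_pts: int
    family_pts: int

    def __post_init__(self) -> None:
        for name, allowed in ITEM_POINT_SETS.items():
            v = getattr(self, name)
            if v not in allowed:
                raise ValueError(f"{name} must be in {allowed}, got {v}")

    @property
    def total(self) -> int:
        return (
            self.age_pts
            + self.bmi_pts
            + self.waist_pts
            + self.pa_pts
            + self.fruitveg_pts
            + self.med_pts
            + self.glucose_hist_pts
            + self.family_pts
        )


def compute_bmi(weight: float, height: float) -> float:
    """Body mass index in kg/m² from weight (kg) and height (cm)."""
    if not weight > 0:
        raise ValueError(f"weight must be > 0, got {weight}")
    if not height > 0:
        raise ValueError(f"height must be > 0, got {height}")
    return weight / (height / 100.0) ** 2


def derive_pa_minutes(commute: float, recreation: float, work: float) -> float:
    """Total daily physical-activity minutes across commute, recreation, work."""
    for name, v in (("commute", commute), ("recreation", recreation), ("work", work)):
        if v < 0:
            raise ValueError(f"{name} minutes must be >= 0, got {v}")
    return commute + recreation + work


def age_points(age: float) -> int:
    if age < 45:
        return 0
    if age < 55:
        return 2
    if age < 65:
        return 3
    return 4


def bmi_points(bmi: float) -> int:
    if bmi < 25:
        return 0
    if bmi <= 30:
        return 1
    return 3


def waist_points(waist: float, sex: str) -> int:
    lo, hi = (94, 102) if sex == "male" else (80, 88)
    if waist < lo:
        return 0
    if waist <= hi:
        return 3
    return 4


def pa_points(minutes_per_day: float) -> int:
    return 0 if minutes_per_day >= 30 else 2


def fruitveg_points(daily: bool) -> int:
    return 0 if daily else 1


def med_points(uses_antihypertensive_med: bool) -> int:
    return 2 if uses_antihypertensive_med else 0


def glucose_history_points(history_high_glucose: bool) -> int:
    return 5 if history_high_glucose else 0


def family_history_points(level: str) -> int:
    return {"none": 0, "second_degree": 3, "first_degree": 5}[level]


def _require(record: ParticipantRecord, item: str) -> object:
    v = getattr(record, item, None)
    if v is None or (isinstance(v, float) and math.isnan(v)):
        raise MissingItemError(f"cannot score FINDRISC: item {item!r} is missing")
    return v


def score_findrisc(record: ParticipantRecord) -> FindriscComponents:
    """Score all eight FINDRISC items for one participant.

    Raises :class:`MissingItemError` naming the first missing item.  The
    total is the plain sum of the eight sub-scores and lies in [0, 26].
    """
    for item in (
        "age",
        "weight",
        "height",
        "waist",
        "sex",
        "uses_antihypertensive_med",
        "history_high_glucose",
        "family_history",
        "pa_minutes_commute",
        "pa_minutes_recreation",
        "pa_minutes_work",
        "fruit_veg_daily",
    ):
        _require(record, item)
    bmi = compute_bmi(record.weight, record.height)
    pa = derive_pa_minutes(
        record.pa_minutes_commute, record.pa_minutes_recreation, record.pa_minutes_work
    )
    return FindriscComponents(
        age_pts=age_points(record.age),
        bmi_pts=bmi_points(bmi),
        waist_pts=waist_points(record.waist, record.sex),
        pa_pts=pa_points(pa),
        fruitveg_pts=fruitveg_points(record.fruit_veg_daily),
        med_pts=med_points(record.uses_antihypertensive_med),
        glucose_hist_pts=glucose_history_points(record.history_high_glucose),
        family_pts=family_history_points(record.family_history),
    )


def score_cohort(df: pd.DataFrame) -> pd.Series:
    """Vectorised FINDRISC totals for a cohort frame (one int per row)."""
    if df.empty:
        return pd.Series([], dtype=int, name="findrisc")
    age = df["age"].to_numpy(float)
    bmi = df["weight"].to_numpy(float) / (df["height"].to_numpy(float) / 100.0) ** 2
    waist = df["waist"].to_numpy(float)
    male = df["sex"].to_numpy() == "male"
    pa = (
        df["pa_minutes_commute"].to_numpy(float)
        + df["pa_minutes_recreation"].to_numpy(float)
        + df["pa_minutes_work"].to_numpy(float)
    )

    pts = np.select([age < 45, age < 55, age < 65], [0, 2, 3], default=4)
    pts = pts + np.select([bmi < 25, bmi <= 30], [0, 1], default=3)
    lo = np.where(male, 94, 80)
    hi = np.where(male, 102, 88)
    pts = pts + np.select([waist < lo, waist <= hi], [0, 3], default=4)
    pts = pts + np.where(pa >= 30, 0, 2)
    pts = pts + np.where(df["fruit_veg_daily"].to_numpy(bool), 0, 1)
    pts = pts + np.where(df["uses_antihypertensive_med"].to_numpy(bool), 2, 0)
    pts = pts + np.where(df["history_high_glucose"].to_numpy(bool), 5, 0)
    fam = df["family_history"].map({"none": 0, "second_degree": 3, "first_degree": 5})
    if fam.isna().any():
        bad = df.loc[fam.isna(), "family_history"].unique().tolist()
        raise ValueError(f"unknown family_history levels: {bad}")
    pts = pts + fam.to_numpy(int)
    return pd.Series(pts, index=df.index, name="findrisc", dtype=int)


def enumerate_component_profiles() -> np.ndarray:
    """All 1728 item-point combinations as a (1728, 8) int array.

    Column order follows :data:`ITEM_POINT_SETS`.  Used for brute-force
    range/decomposition checks and by the synthetic generator to back-fill
    item profiles consistent with a sampled total.
    """
    grids = np.meshgrid(*[np.array(v) for v in ITEM_POINT_SETS.values()], indexing="ij")
    return np.stack([g.ravel() for g in grids], axis=1)
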