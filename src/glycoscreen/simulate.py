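"""Seeded generator of NHANES-like synthetic screening cohorts.

Each subject is drawn from a five-class glycemic mixture (NGT, isolated
IFG, isolated IGT, IFG+IGT, undiagnosed diabetes).  Given the class,
fasting and 2-h post-load glucose are sampled from normals truncated to the
class's defining region — so every generated record classifies back to its
assigned class — HbA1c from a positive-truncated normal, and the FINDRISC
total from a normal truncated to [−0.5, 26.5] and rounded to an integer in
[0, 26].  The eight item sub-scores are then sampled uniformly among the
component combinations summing to that total, and raw questionnaire and
anthropometric fields are back-filled consistent with the sub-scores.
Default class prevalences and class-conditional means/SDs are calibrated to
the NHANES 2005–2010 morning-fasted study sample this package emulates.

HbA1c and FINDRISC are conditionally independent given the class by
default; a per-class Gaussian-copula correlation knob is provided.  Because
the defaults are fully parametric, closed-form "generator truth" for test
operating points is available (see :func:`true_operating_point`) and is the
oracle for parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from glycoscreen.evaluation import BinaryTestSpec
from glycoscreen.glycemia import (
    EXCLUSION_STEPS,
    FPG_DM,
    FPG_IFG,
    GlycemicClass,
    PG2H_DM,
    PG2H_IGT,
)
from glycoscreen.findrisc import enumerate_component_profiles
from glycoscreen.records import COHORT_COLUMNS

CLASS_ORDER = (
    GlycemicClass.NGT,
    GlycemicClass.iIFG,
    GlycemicClass.iIGT,
    GlycemicClass.IFG_IGT,
    GlycemicClass.DM,
)

#: (FPG interval, 2-h PG interval) defining each non-diabetic class; the
#: diabetic region is the union handled separately (FPG- vs 2-h-driven).
_CLASS_REGIONS = {
    GlycemicClass.NGT: ((0.0, FPG_IFG), (0.0, PG2H_IGT)),
    GlycemicClass.iIFG: ((FPG_IFG, FPG_DM), (0.0, PG2H_IGT)),
    GlycemicClass.iIGT: ((0.0, FPG_IFG), (PG2H_IGT, PG2H_DM)),
    GlycemicClass.IFG_IGT: ((FPG_IFG, FPG_DM), (PG2H_IGT, PG2H_DM)),
}

_FINDRISC_LO, _FINDRISC_HI = -0.5, 26.5


@dataclass(frozen=True)
class ClassParams:
    """Class-conditional mean/SD of the four analytes."""

    hba1c: Tuple[float, float]
    findrisc: Tuple[float, float]
    fpg: Tuple[float, float]
    pg2h: Tuple[float, float]


@dataclass(frozen=True)
class CohortConfig:
    """Everything the generator needs; same config + seed → same cohort."""

    n: int
    seed: int = 0
    class_prevalences: Dict[GlycemicClass, float] = field(default_factory=dict)
    class_params: Dict[GlycemicClass, ClassParams] = field(default_factory=dict)
    missing_hba1c_rate: float = 0.0
    missing_fpg_rate: float = 0.0
    missing_pg2h_rate: float = 0.0
    self_reported_diabetes_rate: float = 0.0
    dm_fpg_driven_frac: float = 0.5
    hba1c_findrisc_corr: Dict[GlycemicClass, float] = field(default_factory=dict)
    weight_lognorm_sigma: float = 0.5
    n_cycles: int = 3

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be >= 0")
        prev = [self.class_prevalences.get(c, 0.0) for c in CLASS_ORDER]
        if any(p < 0 for p in prev) or abs(sum(prev) - 1.0) > 1e-9:
            raise ValueError("class prevalences must be >= 0 and sum to 1")
        for c, cp in self.class_params.items():
            for name in ("hba1c", "findrisc", "fpg", "pg2h"):
                _, sd = getattr(cp, name)
                if sd < 0:
                    raise ValueError(f"{c.value} {name} SD must be >= 0")
        for r in (
            self.missing_hba1c_rate,
            self.missing_fpg_rate,
            self.missing_pg2h_rate,
            self.self_reported_diabetes_rate,
        ):
            if not 0 <= r <= 1:
                raise ValueError("missingness/self-report rates must be in [0, 1]")
        if not 0 <= self.dm_fpg_driven_frac <= 1:
            raise ValueError("dm_fpg_driven_frac must be in [0, 1]")
        if self.n_cycles not in (1, 2, 3):
            raise ValueError("n_cycles must be 1, 2 or 3")


def default_config(n: int = 4000, seed: int = 0) -> CohortConfig:
    """Generator defaults calibrated to the emulated NHANES 2005–2010 sample.

    Class prevalences and the class-conditional mean/SD table reproduce the
    study sample's descriptive statistics; missingness and self-reported
    diabetes rates reproduce its eligibility-cascade proportions
    (87, 15, 806 and 99 out of 4893).
    """
    prevalences = {
        GlycemicClass.NGT: 0.5375,
        GlycemicClass.iIFG: 0.2708,
        GlycemicClass.iIGT: 0.0437,
        GlycemicClass.IFG_IGT: 0.0951,
        GlycemicClass.DM: 0.0529,
    }
    params = {
        GlycemicClass.NGT: ClassParams((5.28, 0.35), (7.28, 4.39), (91.43, 5.70), (93.35, 21.80)),
        GlycemicClass.iIFG: ClassParams((5.47, 0.38), (9.02, 4.56), (106.15, 5.04), (104.65, 21.38)),
        GlycemicClass.iIGT: ClassParams((5.43, 0.38), (9.79, 4.31), (93.19, 5.23), (158.35, 14.89)),
        GlycemicClass.IFG_IGT: ClassParams((5.63, 0.38), (11.32, 4.17), (109.26, 6.67), (162.79, 15.74)),
        GlycemicClass.DM: ClassParams((6.24, 1.36), (11.66, 4.16), (133.67, 42.64), (234.46, 76.40)),
    }
    base = 4893.0
    return CohortConfig(
        n=n,
        seed=seed,
        class_prevalences=prevalences,
        class_params=params,
        missing_hba1c_rate=87 / base,
        missing_fpg_rate=15 / base,
        missing_pg2h_rate=806 / base,
        self_reported_diabetes_rate=99 / base,
    )


def _truncnorm(mean: float, sd: float, lo: float, hi: float):
    if sd <= 0:
        raise ValueError("truncated normal needs SD > 0")
    a, b = (lo - mean) / sd, (hi - mean) / sd
    if not a < b:
        raise ValueError(f"infeasible truncation [{lo}, {hi}] for mean {mean}, sd {sd}")
    return stats.truncnorm(a, b, loc=mean, scale=sd)


def _sample_truncnorm(rng, mean, sd, lo, hi, size) -> np.ndarray:
    # inverse-CDF sampling: deterministic under the rng and copula-friendly
    return _truncnorm(mean, sd, lo, hi).ppf(rng.uniform(size=size))


def truncnorm_tail_prob(threshold, mean, sd, lo, hi) -> float:
    """P(X >= threshold) for a normal truncated to [lo, hi]."""
    return float(_truncnorm(mean, sd, lo, hi).sf(threshold))


def findrisc_tail_prob(threshold: float, mean: float, sd: float) -> float:
    """P(rounded truncated-normal FINDRISC total >= threshold)."""
    k = int(np.ceil(threshold))
    if k <= 0:
        return 1.0
    if k > 26:
        return 0.0
    return truncnorm_tail_prob(k - 0.5, mean, sd, _FINDRISC_LO, _FINDRISC_HI)


# ---------------------------------------------------------------------------
# closed-form generator truth

def true_class_mean(config: CohortConfig, cls: GlycemicClass, variable: str) -> float:
    """Expected class-conditional value of ``hba1c`` or ``findrisc``.

    Accounts for the truncation/discretisation the generator applies, so it
    is the exact population mean of the generated samples (unlike the raw
    config mean, which parametrises the untruncated parent normal).
    """
    cp = config.class_params[cls]
    if variable == "hba1c":
        m, s = cp.hba1c
        return float(_truncnorm(m, s, 0.0, np.inf).mean())
    if variable == "findrisc":
        m, s = cp.findrisc
        dist = _truncnorm(m, s, _FINDRISC_LO, _FINDRISC_HI)
        ks = np.arange(27)
        pmf = dist.cdf(ks + 0.5) - dist.cdf(ks - 0.5)
        return float((ks * pmf).sum() / pmf.sum())
    raise ValueError(f"no closed-form mean for variable {variable!r}")


def class_positive_prob(
    config: CohortConfig, cls: GlycemicClass, spec: BinaryTestSpec
) -> float:
    """P(test positive | glycemic class) under the generator.

    Requires the default zero HbA1c–FINDRISC copula correlation, under which
    the two leaf analytes are conditionally independent given the class.
    """
    if config.hba1c_findrisc_corr.get(cls, 0.0) != 0.0:
        raise ValueError("closed-form truth requires zero copula correlation")
    cp = config.class_params[cls]
    if spec.kind == "hba1c_ge":
        m, s = cp.hba1c
        return truncnorm_tail_prob(spec.threshold, m, s, 0.0, np.inf)
    if spec.kind == "findrisc_ge":
        m, s = cp.findrisc
        return findrisc_tail_prob(spec.threshold, m, s)
    pa = class_positive_prob(config, cls, spec.operands[0])
    pb = class_positive_prob(config, cls, spec.operands[1])
    if spec.kind == "parallel_or":
        return 1.0 - (1.0 - pa) * (1.0 - pb)
    return pa * pb  # serial_and


def _target_classes(target: str) -> Tuple[Tuple[GlycemicClass, ...], Tuple[GlycemicClass, ...]]:
    pre = (GlycemicClass.iIFG, GlycemicClass.iIGT, GlycemicClass.IFG_IGT)
    if target == "diabetes":
        return (GlycemicClass.DM,), (GlycemicClass.NGT,) + pre
    if target == "prediabetes":
        return pre, (GlycemicClass.NGT,)
    if target == "iIFG":
        return (GlycemicClass.iIFG,), (GlycemicClass.NGT, GlycemicClass.iIGT, GlycemicClass.IFG_IGT)
    if target == "iIGT":
        return (GlycemicClass.iIGT,), (GlycemicClass.NGT, GlycemicClass.iIFG, GlycemicClass.IFG_IGT)
    raise ValueError(f"unknown target {target!r}")


def true_operating_point(
    config: CohortConfig, spec: BinaryTestSpec, target: str = "diabetes"
) -> Tuple[float, float]:
    """Closed-form (sensitivity %, specificity %) of a test on this generator.

    Mixture-weighted exceedance probabilities over the diseased and control
    class sets of the chosen outcome; the oracle that parameter-recovery
    tests compare pipeline estimates against.
    """
    diseased, controls = _target_classes(target)
    prev = config.class_prevalences

    def mix(classes, fn):
        wts = np.array([prev[c] for c in classes])
        vals = np.array([fn(c) for c in classes])
        return float((wts * vals).sum() / wts.sum())

    se = mix(diseased, lambda c: class_positive_prob(config, c, spec))
    sp = mix(controls, lambda c: 1.0 - class_positive_prob(config, c, spec))
    return 100.0 * se, 100.0 * sp


# ---------------------------------------------------------------------------
# sampling

_PROFILES = enumerate_component_profiles()
_PROFILE_TOTALS = _PROFILES.sum(axis=1)
_PROFILES_BY_TOTAL = {
    t: np.flatnonzero(_PROFILE_TOTALS == t) for t in range(27)
}

_AGE_BANDS = {0: (20.0, 44.99), 2: (45.0, 54.99), 3: (55.0, 64.99), 4: (65.0, 80.0)}
_BMI_BANDS = {0: (19.0, 24.99), 1: (25.0, 30.0), 3: (30.01, 42.0)}
_WAIST_BANDS = {
    "male": {0: (70.0, 93.99), 3: (94.0, 102.0), 4: (102.01, 130.0)},
    "female": {0: (60.0, 79.99), 3: (80.0, 88.0), 4: (88.01, 120.0)},
}
_FAMILY_LEVELS = {0: "none", 3: "second_degree", 5: "first_degree"}


def _band_uniform(rng, pts: np.ndarray, bands: dict) -> np.ndarray:
    lo = np.array([bands[p][0] for p in pts])
    hi = np.array([bands[p][1] for p in pts])
    return rng.uniform(lo, hi)


def _sample_profiles(rng, totals: np.ndarray) -> np.ndarray:
    """Uniformly pick an item-score combination for each requested total."""
    rows = np.empty(len(totals), dtype=int)
    for t in np.unique(totals):
        idx = _PROFILES_BY_TOTAL[int(t)]
        sel = totals == t
        rows[sel] = idx[rng.integers(0, len(idx), size=int(sel.sum()))]
    return _PROFILES[rows]


def generate_cohort(config: CohortConfig) -> Tuple[pd.DataFrame, pd.Series]:
    """Generate a cohort frame plus the truth sidecar of assigned classes.

    The truth series is indexed by participant id and keeps the assigned
    class for every subject, including those later hidden by missingness or
    the self-reported-diabetes flag.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n
    if n == 0:
        empty = pd.DataFrame(columns=COHORT_COLUMNS)
        return empty, pd.Series(dtype=object, name="glycemic_class")

    prev = np.array([config.class_prevalences[c] for c in CLASS_ORDER])
    cls_idx = rng.choice(len(CLASS_ORDER), size=n, p=prev)
    classes = np.array([c.value for c in CLASS_ORDER])[cls_idx]

    fpg = np.empty(n)
    pg2h = np.empty(n)
    hba1c = np.empty(n)
    findrisc_total = np.empty(n, dtype=int)

    for k, cls in enumerate(CLASS_ORDER):
        sel = cls_idx == k
        m = int(sel.sum())
        if m == 0:
            continue
        cp = config.class_params[cls]
        if cls is GlycemicClass.DM:
            fpg_driven = rng.uniform(size=m) < config.dm_fpg_driven_frac
            nf = int(fpg_driven.sum())
            f = np.empty(m)
            g = np.empty(m)
            if nf:
                f[fpg_driven] = _sample_truncnorm(rng, *cp.fpg, FPG_DM, np.inf, nf)
                g[fpg_driven] = _sample_truncnorm(rng, *cp.pg2h, 0.0, np.inf, nf)
            if m - nf:
                f[~fpg_driven] = _sample_truncnorm(rng, *cp.fpg, 0.0, FPG_DM, m - nf)
                g[~fpg_driven] = _sample_truncnorm(rng, *cp.pg2h, PG2H_DM, np.inf, m - nf)
        else:
            (flo, fhi), (glo, ghi) = _CLASS_REGIONS[cls]
            f = _sample_truncnorm(rng, *cp.fpg, flo, fhi, m)
            g = _sample_truncnorm(rng, *cp.pg2h, glo, ghi, m)
        fpg[sel] = f
        pg2h[sel] = g

        # Gaussian copula between HbA1c and the latent FINDRISC total
        rho = config.hba1c_findrisc_corr.get(cls, 0.0)
        z = rng.standard_normal((m, 2))
        z[:, 1] = rho * z[:, 0] + np.sqrt(max(0.0, 1 - rho**2)) * z[:, 1]
        u = stats.norm.cdf(z)
        hba1c[sel] = _truncnorm(*cp.hba1c, 0.0, np.inf).ppf(u[:, 0])
        latent = _truncnorm(*cp.findrisc, _FINDRISC_LO, _FINDRISC_HI).ppf(u[:, 1])
        findrisc_total[sel] = np.clip(np.rint(latent), 0, 26).astype(int)

    profiles = _sample_profiles(rng, findrisc_total)
    age_pts, bmi_pts, waist_pts, pa_pts, fv_pts, med_pts, gh_pts, fam_pts = profiles.T

    sex = np.where(rng.uniform(size=n) < 0.5, "male", "female")
    age = _band_uniform(rng, age_pts, _AGE_BANDS)
    bmi = _band_uniform(rng, bmi_pts, _BMI_BANDS)
    height = np.clip(
        np.where(sex == "male", 175.0, 162.0) + 7.0 * rng.standard_normal(n), 140, 205
    )
    weight = bmi * (height / 100.0) ** 2
    waist = np.where(
        sex == "male",
        _band_uniform(rng, waist_pts, _WAIST_BANDS["male"]),
        _band_uniform(rng, waist_pts, _WAIST_BANDS["female"]),
    )
    pa_total = np.where(pa_pts == 0, rng.uniform(30.0, 150.0, n), rng.uniform(0.0, 29.9, n))
    split = rng.dirichlet(np.ones(3), size=n)
    pa = pa_total[:, None] * split

    miss_h = rng.uniform(size=n) < config.missing_hba1c_rate
    miss_f = rng.uniform(size=n) < config.missing_fpg_rate
    miss_g = rng.uniform(size=n) < config.missing_pg2h_rate
    self_dm = rng.uniform(size=n) < config.self_reported_diabetes_rate

    weights = np.exp(config.weight_lognorm_sigma * rng.standard_normal(n))
    cycles = rng.integers(1, config.n_cycles + 1, size=n)

    ids = np.array([f"S{i:06d}" for i in range(n)])
    df = pd.DataFrame(
        {
            "id": ids,
            "age": age,
            "sex": sex,
            "height": height,
            "weight": weight,
            "waist": waist,
            "uses_antihypertensive_med": med_pts == 2,
            "history_high_glucose": gh_pts == 5,
            "family_history": [_FAMILY_LEVELS[p] for p in fam_pts],
            "pa_minutes_commute": pa[:, 0],
            "pa_minutes_recreation": pa[:, 1],
            "pa_minutes_work": pa[:, 2],
            "fruit_veg_daily": fv_pts == 0,
            "fpg": np.where(miss_f, np.nan, fpg),
            "pg2h": np.where(miss_g, np.nan, pg2h),
            "hba1c": np.where(miss_h, np.nan, hba1c),
            "fasting_hours": rng.uniform(9.0, 16.0, n),
            "self_reported_diabetes": self_dm,
            "survey_weight": weights,
            "survey_cycle": cycles,
        }
    )[COHORT_COLUMNS]
    truth = pd.Series(classes, index=pd.Index(ids, name="id"), name="glycemic_class")
    return df, truth


def exclusion_fixture(
    counts: Union[Sequence[int], Dict[str, int]] = (87, 15, 806, 99),
    total: int = 4893,
) -> pd.DataFrame:
    """Cohort with disjoint defect groups sized to reproduce a cascade tally.

    ``counts`` is either a mapping over the exclusion-step names or a
    4-sequence (missing HbA1c, missing FPG, missing 2-h PG, self-reported
    diabetes).  The remaining ``total − Σcounts`` records are clean, so the
    eligibility cascade retains exactly that many.
    """
    if not isinstance(counts, dict):
        if len(counts) != 4:
            raise ValueError("counts must be 4 integers or a step-name mapping")
        counts = dict(zip(EXCLUSION_STEPS[2:], counts))
    unknown = set(counts) - set(EXCLUSION_STEPS)
    if unknown:
        raise ValueError(f"unknown exclusion steps: {sorted(unknown)}")
    if any(v < 0 for v in counts.values()):
        raise ValueError("counts must be >= 0")
    n_bad = sum(counts.values())
    if n_bad > total:
        raise ValueError(f"defect counts sum to {n_bad} > total {total}")

    df = pd.DataFrame(
        {
            "id": [f"F{i:06d}" for i in range(total)],
            "age": 40.0,
            "sex": "male",
            "height": 175.0,
            "weight": 80.0,
            "waist": 90.0,
            "uses_antihypertensive_med": False,
            "history_high_glucose": False,
            "family_history": "none",
            "pa_minutes_commute": 10.0,
            "pa_minutes_recreation": 20.0,
            "pa_minutes_work": 10.0,
            "fruit_veg_daily": True,
            "fpg": 90.0,
            "pg2h": 100.0,
            "hba1c": 5.4,
            "fasting_hours": 12.0,
            "self_reported_diabetes": False,
            "survey_weight": 1.0,
            "survey_cycle": 1,
        }
    )[COHORT_COLUMNS]

    start = 0
    for step, k in counts.items():
        rows = slice(start, start + k)
        if step == "age_lt_20":
            df.loc[df.index[rows], "age"] = 18.0
        elif step == "fasting_out_of_range":
            df.loc[df.index[rows], "fasting_hours"] = 5.0
        elif step == "missing_hba1c":
            df.loc[df.index[rows], "hba1c"] = np.nan
        elif step == "missing_fpg":
            df.loc[df.index[rows], "fpg"] = np.nan
        elif step == "missing_pg2h":
            df.loc[df.index[rows], "pg2h"] = np.nan
        elif step == "self_reported_diabetes":
            df.loc[df.index[rows], "self_reported_diabetes"] = True
        start += k
    return df


def with_n(config: CohortConfig, n: int, seed: Optional[int] = None) -> CohortConfig:
    """Copy of a config with a new size (and optionally a new seed)."""
    return replace(config, n=n, seed=config.seed if seed is None else seed)
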