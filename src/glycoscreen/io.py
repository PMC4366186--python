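"""Cohort CSV reading/writing and report serialisation.

The cohort CSV has one row per participant with the canonical column set;
missing laboratory values are empty cells.  Reading validates ranges and
categorical levels and reports row-indexed errors.  Reports are written as
2-decimal CSV tables (presentation precision) plus a full-precision JSON
bundle.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from glycoscreen.records import BOOL_COLUMNS, COHORT_COLUMNS, validate_cohort

_TRUE = {"true", "1", "yes", "t"}
_FALSE = {"false", "0", "no", "f"}

#: report columns rounded to 2 decimals in CSV output
_PERCENT_COLS = (
    "sensitivity", "specificity", "ppv", "npv", "ppv_adjusted", "npv_adjusted",
    "sum", "pct_population", "fraction_positive",
)


def _parse_bool_column(s: pd.Series, name: str) -> pd.Series:
    if s.dtype == bool:
        return s
    lowered = s.astype(str).str.strip().str.lower()
    bad = ~lowered.isin(_TRUE | _FALSE)
    if bad.any():
        rows = s.index[bad].tolist()[:10]
        raise ValueError(f"column {name!r}: unparseable booleans at rows {rows}")
    return lowered.isin(_TRUE)


def read_cohort(path: Union[str, Path]) -> pd.DataFrame:
    """Read and validate a cohort CSV; raises with row-indexed diagnostics."""
    path = Path(path)
    if path.stat().st_size == 0:
        raise ValueError(f"{path}: empty input file")
    df = pd.read_csv(path, dtype={"id": str})
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    for c in BOOL_COLUMNS:
        df[c] = _parse_bool_column(df[c], c)
    df = df[COHORT_COLUMNS]
    validate_cohort(df)
    return df


def write_cohort(df: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write a cohort CSV (missing labs as empty cells); round-trip safe."""
    df[COHORT_COLUMNS].to_csv(path, index=False)


def _jsonable(obj):
    if isinstance(obj, pd.DataFrame):
        return json.loads(obj.to_json(orient="records"))
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_report(bundle: dict, outdir: Union[str, Path]) -> None:
    """Write a report bundle: one rounded CSV per table plus report.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, obj in bundle.items():
        if isinstance(obj, pd.DataFrame):
            shown = obj.copy()
            for c in shown.columns:
                if c in _PERCENT_COLS or shown[c].dtype.kind == "f":
                    shown[c] = shown[c].round(2)
            shown.to_csv(outdir / f"{name}.csv", index=False)
    with open(outdir / "report.json", "w") as fh:
        json.dump(_jsonable(bundle), fh, indent=2)
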