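"""CSV readers/writers and table validation for cohort and survival data."""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "read_cohort_table",
    "read_survival_table",
    "write_cohort_table",
    "write_survival_table",
]

REQUIRED_COHORT_COLUMNS = ["animal_id", "strain", "sex", "age_weeks",
                           "WBC", "LY", "LY%", "RBC", "HB", "HCT%",
                           "MCV", "MCH", "MCHC", "PLT"]

_SEX_MAP = {
    "m": "M", "male": "M", "males": "M", "M": "M",
    "f": "F", "female": "F", "females": "F", "F": "F",
}


def read_cohort_table(
    path: str | Path, column_map: Optional[dict[str, str]] = None
) -> pd.DataFrame:
    """Read a cohort CSV, validating required columns.

    ``column_map`` maps source column names to the canonical names (for
    alternate table dialects).  Sex labels are normalised to {M, F}; rows
    with unparseable ages are rejected with their line numbers reported.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in REQUIRED_COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {missing}")

    sex = df["sex"].astype(str).str.strip()
    norm = sex.str.lower().map({k.lower(): v for k, v in _SEX_MAP.items()})
    bad_sex = norm.isna()
    if bad_sex.any():
        raise ValueError(
            f"unrecognised sex label(s): {sorted(sex[bad_sex].unique())}"
        )
    df["sex"] = norm

    ages = pd.to_numeric(df["age_weeks"], errors="coerce")
    bad = ages.isna()
    if bad.any():
        lines = (df.index[bad] + 2).tolist()  # +2: header + 1-based
        warnings.warn(
            f"rejected {int(bad.sum())} row(s) with unparseable age "
            f"(lines {lines[:10]})",
            RuntimeWarning,
            stacklevel=2,
        )
        df = df[~bad]
        ages = ages[~bad]
    df = df.copy()
    df["age_weeks"] = ages.astype(float)
    return df.reset_index(drop=True)


def read_survival_table(path: str | Path) -> pd.DataFrame:
    """Read a survival CSV (animal_id, event_age_weeks, observed)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    if df.empty:
        warnings.warn(f"{path} is empty", RuntimeWarning, stacklevel=2)
        return pd.DataFrame(
            columns=["animal_id", "event_age_weeks", "observed"]
        )
    missing = [
        c for c in ("animal_id", "event_age_weeks", "observed")
        if c not in df.columns
    ]
    if missing:
        raise ValueError(f"missing required column(s): {missing}")
    if not df["observed"].isin([0, 1]).all():
        bad = sorted(df.loc[~df["observed"].isin([0, 1]), "observed"].unique())
        raise ValueError(f"observed flag must be 0 or 1; found {bad}")
    dup = df["animal_id"][df["animal_id"].duplicated()].unique()
    if dup.size:
        raise ValueError(f"duplicate animal_id(s): {sorted(dup.tolist())}")
    df["event_age_weeks"] = df["event_age_weeks"].astype(float)
    df["observed"] = df["observed"].astype(int)
    return df


def write_cohort_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def write_survival_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
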