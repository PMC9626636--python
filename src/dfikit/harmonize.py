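"""CBC preprocessing: dialect harmonisation, strain centering, adult filter.

Different CBC table dialects may lack granulocyte columns; these are
recovered from the count/differential identities

    GR  = WBC - LY - MO
    GR% = 100 - LY% - MO%

Strain baseline differences are removed by subtracting, per strain, the mean
feature vector of that strain's earliest-age group.  Only fully grown
animals (age strictly greater than 25 weeks by default) enter the analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FEATURES",
    "FeatureMatrix",
    "derive_granulocytes",
    "strain_center",
    "filter_adult",
    "assemble_matrix",
]

#: Canonical feature order of the harmonised matrix (fixed, documented).
FEATURES = [
    "GR%", "GR", "HB", "HCT%", "LY%", "LY",
    "MCHC", "MCH", "MCV", "PLT", "RBC", "WBC",
]

#: Name of the boolean QC column set by :func:`derive_granulocytes`.
QC_COLUMN = "qc_valid"


@dataclass
class FeatureMatrix:
    """Harmonised n x 12 matrix in original CBC units.

    ``row_keys`` is a DataFrame aligned with ``values`` carrying at least
    ``animal_id`` and ``age_weeks`` (plus ``strain``/``sex`` when present in
    the source table).
    """

    values: np.ndarray
    row_keys: pd.DataFrame
    columns: tuple = tuple(FEATURES)
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.columns):
            raise ValueError("values must be n x %d" % len(self.columns))
        if np.isnan(self.values).any():
            raise ValueError("FeatureMatrix may not contain missing entries")
        if len(self.row_keys) != self.values.shape[0]:
            raise ValueError("row_keys must align with values")

    def to_frame(self) -> pd.DataFrame:
        df = self.row_keys.reset_index(drop=True).copy()
        for j, c in enumerate(self.columns):
            df[c] = self.values[:, j]
        return df


def derive_granulocytes(table: pd.DataFrame) -> pd.DataFrame:
    """Fill missing granulocyte columns from (WBC, LY, MO) and (LY%, MO%).

    Existing GR/GR% values are left untouched.  Derived values outside their
    physical range (GR < 0 or GR% outside [0, 100]) flag the record invalid
    via the ``qc_valid`` column; such records are dropped downstream by
    :func:`assemble_matrix`.
    """
    df = table.copy()
    if QC_COLUMN not in df.columns:
        df[QC_COLUMN] = True

    for col in ("GR", "GR%"):
        if col not in df.columns:
            df[col] = np.nan

    need_gr = df["GR"].isna()
    if need_gr.any():
        missing = [c for c in ("WBC", "LY", "MO") if c not in df.columns]
        if missing:
            raise ValueError(
                f"cannot derive GR: missing column(s) {missing}"
            )
        derived = df["WBC"] - df["LY"] - df["MO"]
        df.loc[need_gr, "GR"] = derived[need_gr]
        bad = need_gr & (df["GR"] < 0)
        df.loc[bad, QC_COLUMN] = False

    need_pct = df["GR%"].isna()
    if need_pct.any():
        missing = [c for c in ("LY%", "MO%") if c not in df.columns]
        if missing:
            raise ValueError(
                f"cannot derive GR%: missing column(s) {missing}"
            )
        derived = 100.0 - df["LY%"] - df["MO%"]
        df.loc[need_pct, "GR%"] = derived[need_pct]
        bad = need_pct & ((df["GR%"] < 0) | (df["GR%"] > 100))
        df.loc[bad, QC_COLUMN] = False
    return df


def strain_center(table: pd.DataFrame) -> pd.DataFrame:
    """Subtract each strain's earliest-age mean feature vector.

    The earliest age is the minimal age present for that strain in the
    given table (computed after any upstream filtering), and the centering
    pools sexes within the strain.
    """
    if "strain" not in table.columns:
        raise ValueError("table must carry a 'strain' column")
    df = table.copy()
    feats = [c for c in FEATURES if c in df.columns]
    for strain, grp in df.groupby("strain", sort=False):
        if len(grp) == 1:
            warnings.warn(
                f"strain {strain!r} has a single record; centering collapses "
                "it to zero",
                RuntimeWarning,
                stacklevel=2,
            )
        t0 = grp["age_weeks"].min()
        base = grp.loc[grp["age_weeks"] == t0, feats].mean(axis=0)
        df.loc[grp.index, feats] = grp[feats] - base
    return df


def filter_adult(table: pd.DataFrame, threshold: float = 25.0) -> pd.DataFrame:
    """Keep rows with ``age_weeks`` strictly greater than ``threshold``."""
    out = table[table["age_weeks"] > threshold]
    if out.empty:
        raise ValueError(
            f"no records remain with age_weeks > {threshold} weeks"
        )
    return out.copy()


def assemble_matrix(table: pd.DataFrame) -> FeatureMatrix:
    """Assemble the n x 12 matrix, dropping incomplete or invalid rows."""
    df = table
    missing_cols = [c for c in FEATURES if c not in df.columns]
    if missing_cols:
        raise ValueError(f"table lacks required feature column(s) {missing_cols}")
    ok = ~df[FEATURES].isna().any(axis=1)
    if QC_COLUMN in df.columns:
        ok &= df[QC_COLUMN].astype(bool)
    n_dropped = int((~ok).sum())
    frac = n_dropped / max(len(df), 1)
    if frac > 0.20:
        warnings.warn(
            f"dropping {frac:.1%} of records (expected < 2% on clean data)",
            RuntimeWarning,
            stacklevel=2,
        )
    kept = df.loc[ok]
    key_cols = [
        c for c in ("animal_id", "strain", "sex", "age_weeks") if c in df.columns
    ]
    return FeatureMatrix(
        values=kept[FEATURES].to_numpy(dtype=float),
        row_keys=kept[key_cols].reset_index(drop=True),
        n_dropped=n_dropped,
    )
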