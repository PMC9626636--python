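"""Pair construction, dFI scoring, age adjustment and model evaluation."""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ..harmonize import FEATURES, FeatureMatrix
from .model import AEARModel

__all__ = [
    "make_pairs",
    "score_dfi",
    "age_adjust_dfi",
    "evaluate_reconstruction",
    "fit_growth_exponent",
    "autocorrelation",
]


def make_pairs(
    table: pd.DataFrame,
    delta_t: float = 26.0,
    tolerance: float = 4.0,
    age_window: tuple[float, float] = (26.0, 104.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Indices of same-animal consecutive record pairs with the target gap.

    Both records must fall inside ``age_window`` and the age gap must lie in
    ``[delta_t - tolerance, delta_t + tolerance]``.  Returns two aligned
    integer index arrays into ``table`` (present, future).
    """
    lo, hi = age_window
    dfw = table[(table["age_weeks"] >= lo) & (table["age_weeks"] <= hi)]
    idx_n, idx_n1 = [], []
    for _, grp in dfw.groupby("animal_id", sort=False):
        order = grp.sort_values("age_weeks")
        rows = order.index.to_numpy()
        ages = order["age_weeks"].to_numpy(dtype=float)
        for k in range(len(rows) - 1):
            gap = ages[k + 1] - ages[k]
            if delta_t - tolerance <= gap <= delta_t + tolerance:
                idx_n.append(rows[k])
                idx_n1.append(rows[k + 1])
    if not idx_n:
        warnings.warn("no longitudinal pairs found", RuntimeWarning, stacklevel=2)
    return np.asarray(idx_n, dtype=int), np.asarray(idx_n1, dtype=int)


def score_dfi(
    model: AEARModel,
    records: pd.DataFrame | FeatureMatrix,
    adjust: bool = False,
) -> pd.DataFrame:
    """Score records; rows missing any of the 12 features are skipped.

    Returns a DataFrame with ``animal_id, age_weeks, sex (when present),
    dfi`` and, when ``adjust`` is requested, ``dfi_age_adjusted``.
    """
    if isinstance(records, FeatureMatrix):
        df = records.to_frame()
    else:
        df = records
    missing_cols = [c for c in FEATURES if c not in df.columns]
    if missing_cols:
        raise ValueError(f"records lack feature column(s) {missing_cols}")
    complete = ~df[FEATURES].isna().any(axis=1)
    n_skipped = int((~complete).sum())
    if n_skipped:
        warnings.warn(
            f"skipped {n_skipped} record(s) with missing features",
            RuntimeWarning,
            stacklevel=2,
        )
    sub = df.loc[complete]
    values = model.dfi(sub[FEATURES].to_numpy(dtype=float))
    out_cols = {}
    for c in ("animal_id", "age_weeks", "sex"):
        if c in sub.columns:
            out_cols[c] = sub[c].to_numpy()
    out_cols["dfi"] = values
    out = pd.DataFrame(out_cols).reset_index(drop=True)
    if adjust:
        out = age_adjust_dfi(out)
    return out


def age_adjust_dfi(
    scores: pd.DataFrame,
    grouping: Sequence[str] = ("sex", "age_weeks"),
    age_bins: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Subtract the mean dFI of each (sex, age-group) cell.

    Adjusted values have exactly zero mean within every group; singleton
    groups get an adjusted value of 0 with a warning.
    """
    df = scores.copy()
    keys = [g for g in grouping if g in df.columns]
    if "age_weeks" in keys and age_bins is not None:
        df["_age_group"] = np.digitize(df["age_weeks"], np.asarray(age_bins))
        keys = [k if k != "age_weeks" else "_age_group" for k in keys]
    if not keys:
        raise ValueError("no grouping columns present in scores")
    sizes = df.groupby(keys)["dfi"].transform("size")
    if (sizes == 1).any():
        warnings.warn(
            f"{int((sizes == 1).sum())} singleton group(s); adjusted value "
            "set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
    means = df.groupby(keys)["dfi"].transform("mean")
    df["dfi_age_adjusted"] = df["dfi"] - means
    return df.drop(columns=["_age_group"], errors="ignore")


def evaluate_reconstruction(
    model: AEARModel, matrix: FeatureMatrix
) -> pd.DataFrame:
    """Per-feature RMSE and R^2 of the autoencoder in original units.

    R^2 = 1 - SS_res/SS_tot (unbounded below); NaN for zero-variance
    features.  The returned frame carries an ``average`` row.
    """
    X = matrix.values
    Xhat = model.reconstruct(X)
    res = X - Xhat
    rmse = np.sqrt((res**2).mean(axis=0))
    ss_res = (res**2).sum(axis=0)
    ss_tot = ((X - X.mean(axis=0)) ** 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, np.nan)
    if np.isnan(r2).any():
        warnings.warn(
            "R^2 undefined for zero-variance feature(s)", RuntimeWarning,
            stacklevel=2,
        )
    df = pd.DataFrame(
        {"feature": list(matrix.columns), "rmse": rmse, "r2": r2}
    )
    avg = pd.DataFrame(
        {"feature": ["average"], "rmse": [rmse.mean()], "r2": [np.nanmean(r2)]}
    )
    return pd.concat([df, avg], ignore_index=True)


def fit_growth_exponent(
    ages: np.ndarray,
    means: np.ndarray,
    sems: np.ndarray,
    lifespan_cutoff: float,
) -> dict:
    """Weighted exponential fit ``zbar * exp(alpha t) + z0`` to group means.

    Groups at or beyond ``lifespan_cutoff`` are excluded (late-life
    saturation is outside the exponential regime).  Returns point estimates
    with standard errors and 95% CIs from the weighted least-squares
    covariance.
    """
    ages = np.asarray(ages, dtype=float)
    means = np.asarray(means, dtype=float)
    sems = np.asarray(sems, dtype=float)
    keep = ages < lifespan_cutoff
    if keep.sum() < 4:
        raise ValueError("need >= 4 age groups below the lifespan cutoff")
    t, y, s = ages[keep], means[keep], sems[keep]
    s = np.where(s > 0, s, np.nanmax(s[s > 0]) if (s > 0).any() else 1.0)

    def f(tt, zbar, alpha, z0):
        return zbar * np.exp(alpha * tt) + z0

    span = max(y.max() - y.min(), 1e-12)
    p0 = (span / max(np.exp(0.02 * t.max()) - 1, 1e-9), 0.02, y.min())
    try:
        popt, pcov = optimize.curve_fit(
            f, t, y, p0=p0, sigma=s, absolute_sigma=True, maxfev=20000
        )
    except RuntimeError as exc:  # pragma: no cover - defensive
        raise RuntimeError(f"growth-exponent fit did not converge: {exc}")
    se = np.sqrt(np.diag(pcov))
    ci = 1.96 * se
    return {
        "zbar": popt[0], "alpha": popt[1], "z0": popt[2],
        "zbar_se": se[0], "alpha_se": se[1], "z0_se": se[2],
        "alpha_ci": (popt[1] - ci[1], popt[1] + ci[1]),
        "n_groups": int(keep.sum()),
    }


def autocorrelation(
    scores: pd.DataFrame,
    lags: Sequence[float],
    tolerance: float = 4.0,
    value_column: str = "dfi_age_adjusted",
) -> pd.DataFrame:
    """Pearson correlation of age-adjusted dFI across same-animal pairs.

    One row per requested lag; lags with fewer than 3 pairs are skipped
    with a warning.
    """
    if value_column not in scores.columns:
        scores = age_adjust_dfi(scores)
    rows = []
    for lag in lags:
        a_vals, b_vals = [], []
        for _, grp in scores.groupby("animal_id", sort=False):
            order = grp.sort_values("age_weeks")
            ages = order["age_weeks"].to_numpy(dtype=float)
            vals = order[value_column].to_numpy(dtype=float)
            for i in range(len(ages)):
                for j in range(i + 1, len(ages)):
                    if abs((ages[j] - ages[i]) - lag) <= tolerance:
                        a_vals.append(vals[i])
                        b_vals.append(vals[j])
        if len(a_vals) < 3:
            warnings.warn(
                f"lag {lag}: fewer than 3 pairs, skipped", RuntimeWarning,
                stacklevel=2,
            )
            continue
        r, p = stats.pearsonr(a_vals, b_vals)
        rows.append({"lag": lag, "pearson_r": r, "p": p, "n_pairs": len(a_vals)})
    return pd.DataFrame(rows, columns=["lag", "pearson_r", "p", "n_pairs"])
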