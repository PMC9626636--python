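"""Mortality analytics.

Censoring-record construction for cohorts with repeated CBC sampling,
censored maximum-likelihood Gompertz fitting, Kaplan--Meier and
Nelson--Aalen estimators (via lifelines), kernel-smoothed hazard with a
late-life plateau check against the Gompertz exponent, a Cox
proportional-hazards benchmark and rank tests of predictors against
remaining lifespan.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter, NelsonAalenFitter
from lifelines.exceptions import ConvergenceError
from scipy import integrate, optimize, stats

from .core_model import HazardCurve, SurvivalCurve

__all__ = [
    "GompertzParams",
    "CoxModel",
    "build_censoring",
    "fit_gompertz",
    "sample_gompertz",
    "kaplan_meier",
    "nelson_aalen_hazard",
    "plateau_check",
    "cox_ph",
    "lifespan_rank_correlation",
]


@dataclass
class GompertzParams:
    """Fitted Gompertz law ``M(t) = M0 * exp(alpha_g t)``."""

    M0: float
    alpha_g: float
    mean_lifespan: float
    M0_se: float = float("nan")
    alpha_g_se: float = float("nan")
    n_events: int = 0

    def __post_init__(self) -> None:
        if not self.M0 > 0:
            raise ValueError("M0 must be > 0")

    def hazard(self, t):
        return self.M0 * np.exp(self.alpha_g * np.asarray(t, dtype=float))

    def cumulative_hazard(self, t):
        t = np.asarray(t, dtype=float)
        a = self.alpha_g
        if abs(a) < 1e-12:
            return self.M0 * t
        return self.M0 * np.expm1(a * t) / a

    def survival(self, t):
        return np.exp(-self.cumulative_hazard(t))


@dataclass
class CoxModel:
    coefficients: pd.Series
    linear_predictor: np.ndarray  # log-hazard ratio per animal
    fitter: CoxPHFitter

    def predict(self, covariates: pd.DataFrame) -> np.ndarray:
        cols = list(self.coefficients.index)
        return covariates[cols].to_numpy(dtype=float) @ self.coefficients.to_numpy()


def build_censoring(
    cohort: pd.DataFrame, deaths: pd.DataFrame
) -> tuple[pd.DataFrame, dict]:
    """Combine death records with measurement-based censoring.

    Animals with a recorded death get an observed event at the death age.
    Animals without a death record and with at least two measurements are
    treated as lost at their last measurement age; animals with a single
    measurement and no death record are excluded (assumed sacrificed at
    collection).
    """
    death_map = (
        deaths.set_index("animal_id")["event_age_weeks"].to_dict()
        if len(deaths)
        else {}
    )
    observed_flags = (
        deaths.set_index("animal_id")["observed"].to_dict()
        if "observed" in deaths.columns and len(deaths)
        else {}
    )
    rows = []
    n_obs = n_cens = n_excl = 0
    for animal, grp in cohort.groupby("animal_id", sort=False):
        if animal in death_map and observed_flags.get(animal, 1) == 1:
            rows.append(
                {"animal_id": animal,
                 "event_age_weeks": float(death_map[animal]),
                 "observed": 1}
            )
            n_obs += 1
        elif len(grp) >= 2:
            rows.append(
                {"animal_id": animal,
                 "event_age_weeks": float(grp["age_weeks"].max()),
                 "observed": 0}
            )
            n_cens += 1
        else:
            n_excl += 1
    surv = pd.DataFrame(rows, columns=["animal_id", "event_age_weeks", "observed"])
    report = {"observed": n_obs, "censored": n_cens, "excluded": n_excl}
    return surv, report


def _gompertz_negloglik(theta: np.ndarray, t: np.ndarray, d: np.ndarray) -> float:
    log_m0, a = theta
    m0 = math.exp(log_m0)
    if abs(a) < 1e-12:
        cumh = m0 * t
    else:
        cumh = m0 * np.expm1(a * t) / a
    ll = np.sum(d * (log_m0 + a * t)) - np.sum(cumh)
    return -ll


def fit_gompertz(surv: pd.DataFrame, min_events: int = 30) -> GompertzParams:
    """Censored MLE of the Gompertz hazard with observed-information SEs.

    ``mean_lifespan`` is the mean of the fitted death-time distribution,
    computed by numerical integration of the fitted survival function.
    """
    t = surv["event_age_weeks"].to_numpy(dtype=float)
    d = surv["observed"].to_numpy(dtype=int)
    n_events = int(d.sum())
    if n_events < min_events:
        raise ValueError(f"need >= {min_events} observed events, got {n_events}")

    rate0 = n_events / max(t.sum(), 1e-9)
    best = None
    for a0 in (0.001, 0.01, 0.05, 0.1):
        x0 = np.array([math.log(rate0) - a0 * np.median(t), a0])
        res = optimize.minimize(
            _gompertz_negloglik, x0, args=(t, d), method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-10, "maxiter": 5000},
        )
        if best is None or res.fun < best.fun:
            best = res
    res = optimize.minimize(
        _gompertz_negloglik, best.x, args=(t, d), method="BFGS",
        options={"gtol": 1e-8},
    )
    if not (res.success or best.success):
        raise RuntimeError(
            f"Gompertz MLE did not converge: {res.message}; trace: {res}"
        )
    theta = res.x if res.fun <= best.fun else best.x
    log_m0, a = theta
    m0 = math.exp(log_m0)

    # observed information via central finite differences in (log M0, a)
    h = np.array([1e-5, 1e-6])
    H = np.zeros((2, 2))
    for i in range(2):
        for j in range(2):
            ei = np.zeros(2); ei[i] = h[i]
            ej = np.zeros(2); ej[j] = h[j]
            H[i, j] = (
                _gompertz_negloglik(theta + ei + ej, t, d)
                - _gompertz_negloglik(theta + ei - ej, t, d)
                - _gompertz_negloglik(theta - ei + ej, t, d)
                + _gompertz_negloglik(theta - ei - ej, t, d)
            ) / (4 * h[i] * h[j])
    try:
        cov = np.linalg.inv(H)
        se_log_m0, se_a = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:  # pragma: no cover
        se_log_m0 = se_a = float("nan")

    gp_tmp = GompertzParams(M0=m0, alpha_g=a, mean_lifespan=0.0, n_events=n_events)
    upper = 5000.0 if a <= 0 else max(10.0 / max(a, 1e-6), 2 * t.max())
    mean_ls, _ = integrate.quad(lambda s: float(gp_tmp.survival(s)), 0, upper,
                                limit=200)
    return GompertzParams(
        M0=m0,
        alpha_g=a,
        mean_lifespan=mean_ls,
        M0_se=m0 * se_log_m0,  # delta method from log scale
        alpha_g_se=se_a,
        n_events=n_events,
    )


def sample_gompertz(
    m0: float, alpha: float, n: int, seed: int = 0
) -> np.ndarray:
    """Inverse-CDF samples of Gompertz death times (simulation oracle)."""
    rng = np.random.Generator(np.random.Philox(seed))
    u = rng.random(n)
    if abs(alpha) < 1e-12:
        return -np.log(u) / m0
    arg = 1.0 - alpha * np.log(u) / m0
    return np.log(arg) / alpha


def kaplan_meier(surv: pd.DataFrame) -> SurvivalCurve:
    """Product-limit estimator with Greenwood 95% confidence bounds."""
    kmf = KaplanMeierFitter()
    kmf.fit(surv["event_age_weeks"], surv["observed"])
    times = kmf.survival_function_.index.to_numpy(dtype=float)
    est = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
    ci = kmf.confidence_interval_
    return SurvivalCurve(
        times=times,
        survival=est,
        ci_low=ci.iloc[:, 0].to_numpy(dtype=float),
        ci_high=ci.iloc[:, 1].to_numpy(dtype=float),
    )


def _epanechnikov(u: np.ndarray) -> np.ndarray:
    return np.where(np.abs(u) <= 1.0, 0.75 * (1.0 - u**2), 0.0)


def nelson_aalen_hazard(
    surv: pd.DataFrame,
    bandwidth: float = 10.0,
    grid: Optional[np.ndarray] = None,
) -> HazardCurve:
    """Nelson--Aalen cumulative hazard and a kernel-smoothed hazard rate.

    The hazard is the Epanechnikov-kernel derivative of the cumulative
    hazard increments, renormalised near the data boundaries; 95% CIs
    propagate the counting-process variance of the increments.
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be > 0")
    naf = NelsonAalenFitter(nelson_aalen_smoothing=False)
    naf.fit(surv["event_age_weeks"], surv["observed"])
    ch = naf.cumulative_hazard_
    event_times = ch.index.to_numpy(dtype=float)
    cumhaz = ch.iloc[:, 0].to_numpy(dtype=float)
    dH = np.diff(np.concatenate([[0.0], cumhaz]))

    # counting-process variance increments d_i / n_i^2 per event time
    t_all = surv["event_age_weeks"].to_numpy(dtype=float)
    d_all = surv["observed"].to_numpy(dtype=int)
    order = np.argsort(t_all, kind="stable")
    ts, ds = t_all[order], d_all[order]
    var_inc = np.zeros_like(event_times)
    n_at_risk_total = len(ts)
    for i, et in enumerate(event_times):
        n_i = n_at_risk_total - np.searchsorted(ts, et, side="left")
        d_i = int(ds[(ts == et)].sum())
        if n_i > 0:
            var_inc[i] = d_i / n_i**2
    if grid is None:
        grid = np.linspace(event_times.min(), event_times.max(), 200)
    grid = np.asarray(grid, dtype=float)

    tmin, tmax = t_all.min(), event_times.max()
    u = (grid[:, None] - event_times[None, :]) / bandwidth
    K = _epanechnikov(u) / bandwidth
    # boundary renormalisation: divide by the kernel mass inside the data range
    lo = np.maximum((grid - tmax) / bandwidth, -1.0)
    hi = np.minimum((grid - tmin) / bandwidth, 1.0)

    def _mass(a, b):
        F = lambda x: 0.75 * (x - x**3 / 3.0) + 0.5
        return np.clip(F(b) - F(a), 1e-9, None)

    mass = _mass(lo, hi)
    hz = (K @ dH) / mass
    var = (K**2 @ var_inc) / mass**2
    se = np.sqrt(var)

    cum_grid = np.interp(grid, event_times, cumhaz, left=0.0)
    at_risk = np.array([(t_all >= g).sum() for g in grid], dtype=float)
    return HazardCurve(
        times=grid,
        hazard=np.clip(hz, 0.0, None),
        cumhaz=cum_grid,
        ci_low=np.clip(hz - 1.96 * se, 0.0, None),
        ci_high=hz + 1.96 * se,
        at_risk=at_risk,
    )


def plateau_check(
    hazard: HazardCurve,
    gompertz: GompertzParams,
    window: Optional[tuple[float, float]] = None,
    min_at_risk: int = 20,
) -> dict:
    """Ratio of late-life smoothed hazard to the Gompertz exponent.

    The default window starts at ``t_bar + 2/alpha_g`` and runs to the last
    estimated point.  The theoretical expectation at the plateau is 1.
    """
    if gompertz.alpha_g <= 0:
        raise ValueError(
            "plateau ratio undefined for non-positive Gompertz exponent"
        )
    if window is None:
        start = gompertz.mean_lifespan + 2.0 / gompertz.alpha_g
        window = (start, float(hazard.times.max()))
    lo, hi = window
    mask = (hazard.times >= lo) & (hazard.times <= hi)
    if not mask.any():
        raise ValueError(
            f"hazard curve does not extend into the window [{lo:.1f}, {hi:.1f}]"
        )
    if hazard.at_risk is not None and hazard.at_risk[mask].max() < min_at_risk:
        warnings.warn(
            f"fewer than {min_at_risk} animals at risk in the plateau window; "
            "confidence interval will be wide",
            RuntimeWarning,
            stacklevel=2,
        )
    m = hazard.hazard[mask].mean()
    ratio = m / gompertz.alpha_g
    if hazard.ci_low is not None:
        lo_r = hazard.ci_low[mask].mean() / gompertz.alpha_g
        hi_r = hazard.ci_high[mask].mean() / gompertz.alpha_g
    else:  # pragma: no cover
        lo_r = hi_r = float("nan")
    return {"ratio": ratio, "ci": (lo_r, hi_r), "window": window,
            "mean_hazard": m}


def cox_ph(
    covariates: pd.DataFrame,
    surv: pd.DataFrame,
    penalizer: float = 0.0,
) -> CoxModel:
    """Cox proportional-hazards fit (Efron ties) on animal-level covariates.

    ``covariates`` must be indexed/keyed by ``animal_id`` matching ``surv``.
    The linear predictor (log-hazard ratio) is returned per animal.
    """
    cov = covariates.copy()
    if "animal_id" in cov.columns:
        cov = cov.set_index("animal_id")
    cov = cov.loc[surv["animal_id"]]
    const = [c for c in cov.columns if cov[c].nunique() <= 1]
    if const:
        raise ValueError(f"constant covariate(s) {const} not allowed")
    df = cov.reset_index(drop=True)
    df["event_age_weeks"] = surv["event_age_weeks"].to_numpy(dtype=float)
    df["observed"] = surv["observed"].to_numpy(dtype=int)
    cph = CoxPHFitter(penalizer=penalizer)
    try:
        cph.fit(df, duration_col="event_age_weeks", event_col="observed")
    except ConvergenceError as exc:
        raise RuntimeError(
            "Cox PH fit failed to converge (possible perfect separation); "
            "retry with a ridge penalty via the `penalizer` argument"
        ) from exc
    coefs = cph.params_
    lp = cov[list(coefs.index)].to_numpy(dtype=float) @ coefs.to_numpy()
    return CoxModel(coefficients=coefs, linear_predictor=lp, fitter=cph)


def lifespan_rank_correlation(
    scores: pd.DataFrame,
    surv: pd.DataFrame,
    cohort_keys: Sequence[str] = ("sex", "age_weeks"),
    value_column: str = "dfi",
    min_n: int = 10,
) -> pd.DataFrame:
    """Spearman rank correlation of a predictor with death age per cohort.

    Cohorts are (sex, measurement-age) cells; only animals with observed
    deaths contribute.  Cohorts below ``min_n`` are skipped and reported
    with NaN statistics.  Tied predictor values are handled by midranks
    (scipy default).
    """
    deaths = surv[surv["observed"] == 1].set_index("animal_id")[
        "event_age_weeks"
    ]
    df = scores.copy()
    df = df[df["animal_id"].isin(deaths.index)]
    df["death_age"] = deaths.loc[df["animal_id"]].to_numpy()
    rows = []
    for key, grp in df.groupby(list(cohort_keys), sort=True):
        key = key if isinstance(key, tuple) else (key,)
        if len(grp) < min_n:
            rows.append(
                dict(zip(cohort_keys, key))
                | {"n": len(grp), "spearman_rho": np.nan, "p": np.nan,
                   "skipped": True}
            )
            continue
        rho, p = stats.spearmanr(grp[value_column], grp["death_age"])
        rows.append(
            dict(zip(cohort_keys, key))
            | {"n": len(grp), "spearman_rho": rho, "p": p, "skipped": False}
        )
    return pd.DataFrame(rows)
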