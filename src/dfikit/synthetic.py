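"""Synthetic multi-strain CBC cohort generator.

Emulates the sampling design of open-access mouse phenome CBC tables: several
strains with distinct baselines, repeated visits at fixed ages, a shared
latent order parameter per animal driving all features, independent
per-feature noise, deaths from the latent blow-up and optional administrative
censoring.  Every downstream module is tested against cohorts produced here,
so the generator also returns the true latent values per visit.

The 12 canonical features (see :data:`dfikit.harmonize.FEATURES`) are linear
in the latent state:  ``x_i = mu_i + b_i * z + noise_i``.  Monocyte columns
are derived through the exact count/differential identities

    MO  = WBC - LY - GR,        MO% = 100 - LY% - GR%,

so that granulocyte recovery from (WBC, LY, MO) round-trips exactly.
Table dialects with granulocyte or monocyte columns suppressed can be
emitted to exercise that recovery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .core_model import LangevinParams, simulate_cohort
from .harmonize import FEATURES

__all__ = ["CohortConfig", "generate_cohort", "write_cohort", "DEFAULT_BASELINE",
           "DEFAULT_LOADINGS", "DEFAULT_NOISE_SD", "cubic_warp"]

#: Baseline values in canonical feature order
#: [GR%, GR, HB, HCT%, LY%, LY, MCHC, MCH, MCV, PLT, RBC, WBC]
DEFAULT_BASELINE = np.array(
    [25.0, 2.5, 14.0, 45.0, 65.0, 6.5, 31.0, 15.0, 50.0, 900.0, 9.0, 10.0]
)

#: Latent loadings in CBC units per dFI-unit (aging shifts counts toward the
#: myeloid lineage and away from red-cell mass).  Scaled for a latent SD of
#: order 1-2 over the default visit schedule.
DEFAULT_LOADINGS = np.array(
    [1.0, 0.02, -0.15, -0.5, -1.0, -0.12, -0.2, -0.1, 0.25, 15.0, -0.15, -0.14]
)

#: Per-feature measurement noise SD in CBC units.
DEFAULT_NOISE_SD = np.array(
    [1.0, 0.15, 0.2, 0.6, 1.0, 0.2, 0.3, 0.2, 0.4, 25.0, 0.2, 0.25]
)

_I_GRP, _I_GR = 0, 1
_I_LYP, _I_LY = 4, 5
_I_WBC = 11

#: Column order of emitted cohort tables.
TABLE_COLUMNS = [
    "animal_id", "strain", "sex", "age_weeks",
    "WBC", "LY", "LY%", "GR", "GR%", "MO", "MO%",
    "RBC", "HB", "HCT%", "MCV", "MCH", "MCHC", "PLT",
]


def cubic_warp(strength: float = 0.15) -> Callable[[np.ndarray, np.ndarray], np.ndarray]:
    """Monotone per-feature distortion for probing non-linear recovery.

    Applies ``m + d + strength * d^3 / scale^2`` where ``d`` is the deviation
    from the column median ``m`` and ``scale`` the column MAD-based scale;
    strictly increasing for any ``strength >= 0``.
    """

    def warp(values: np.ndarray, baseline: np.ndarray) -> np.ndarray:
        d = values - baseline
        scale = np.maximum(np.std(d, axis=0, keepdims=True), 1e-9)
        return baseline + d + strength * d**3 / scale**2

    return warp


@dataclass
class CohortConfig:
    strains: Sequence[tuple[str, np.ndarray]] = field(
        default_factory=lambda: [("S1", DEFAULT_BASELINE.copy())]
    )
    n_per_strain_sex: int = 50
    loadings: np.ndarray = field(default_factory=lambda: DEFAULT_LOADINGS.copy())
    feature_noise_sd: np.ndarray = field(default_factory=lambda: DEFAULT_NOISE_SD.copy())
    langevin: LangevinParams = field(
        default_factory=lambda: LangevinParams(
            alpha=0.03, g=0.0, noise_power=5e-4, z_init=0.1
        )
    )
    visit_ages: Sequence[float] = (26.0, 52.0, 78.0, 104.0)
    pair_interval: float = 26.0
    emit_granulocytes: bool = True
    emit_monocytes: bool = True
    warp: Optional[Callable[[np.ndarray, np.ndarray], np.ndarray]] = None
    censor_rate: float = 0.0  # 1/week, independent exponential censoring clock
    sim_step: float = 0.05
    horizon: Optional[float] = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.loadings = np.asarray(self.loadings, dtype=float)
        self.feature_noise_sd = np.asarray(self.feature_noise_sd, dtype=float)
        ages = np.asarray(self.visit_ages, dtype=float)
        if ages.size == 0 or not np.all(np.diff(ages) > 0):
            raise ValueError("visit_ages must be non-empty and strictly increasing")
        if np.any(self.feature_noise_sd < 0):
            raise ValueError("feature_noise_sd must be >= 0")
        if self.loadings.shape != (12,) or self.feature_noise_sd.shape != (12,):
            raise ValueError("loadings and feature_noise_sd must be 12-vectors")
        if not (self.emit_granulocytes or self.emit_monocytes):
            raise ValueError("at least one of granulocyte/monocyte columns required")
        self._validate_positivity()

    def _latent_sd_max(self) -> float:
        p = self.langevin
        t_max = float(max(self.visit_ages))
        if p.alpha > 0 and p.noise_power > 0:
            var = p.noise_power / (2 * p.alpha) * (np.exp(2 * p.alpha * t_max) - 1)
        else:
            var = p.noise_power * t_max
        mean = abs(p.z_init) * np.exp(max(p.alpha, 0.0) * t_max)
        return float(np.sqrt(var) + mean)

    def _validate_positivity(self) -> None:
        """Baselines must keep features non-negative at 5 latent SDs."""
        sd5 = 5.0 * self._latent_sd_max()
        for name, mu in self.strains:
            mu = np.asarray(mu, dtype=float)
            if mu.shape != (12,):
                raise ValueError(f"baseline for strain {name!r} must be a 12-vector")
            low = mu - np.abs(self.loadings) * sd5
            bad = np.nonzero(low < 0)[0]
            if bad.size:
                raise ValueError(
                    f"strain {name!r}: feature {FEATURES[bad[0]]!r} may go "
                    "negative at 5 latent SDs"
                )
            mo = mu[_I_WBC] - mu[_I_LY] - mu[_I_GR]
            mo_load = (
                self.loadings[_I_WBC] - self.loadings[_I_LY] - self.loadings[_I_GR]
            )
            if mo - abs(mo_load) * sd5 < 0:
                raise ValueError(
                    f"strain {name!r}: feature 'MO' may go negative at 5 latent SDs"
                )


def generate_cohort(
    config: CohortConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate a cohort table, a survival table and the true latent record.

    Returns
    -------
    cohort : DataFrame
        One row per surviving animal per visit, columns
        :data:`TABLE_COLUMNS` minus the suppressed dialect columns.
    survival : DataFrame
        ``animal_id, event_age_weeks, observed`` (1 = death from latent
        blow-up, 0 = censored).
    latent : DataFrame
        ``animal_id, age_weeks, z_true`` for oracle testing only.
    """
    rng = np.random.Generator(np.random.Philox(config.seed))
    ages = np.asarray(config.visit_ages, dtype=float)
    horizon = (
        config.horizon
        if config.horizon is not None
        else float(ages[-1]) + 2.0 * config.pair_interval
    )

    cohort_rows = []
    surv_rows = []
    latent_rows = []
    for s_idx, (strain, mu) in enumerate(config.strains):
        mu = np.asarray(mu, dtype=float)
        for sex in ("M", "F"):
            n = config.n_per_strain_sex
            sub_seed = int(rng.integers(0, 2**63 - 1))
            # reflection at 0 belongs to the mortal (g > 0) process; pure
            # linear cohorts keep the free Gaussian latent so the rank-1
            # covariance structure is exact
            death_times, z_visits = simulate_cohort(
                config.langevin,
                n=n,
                horizon=horizon,
                step=config.sim_step,
                seed=sub_seed,
                visit_ages=ages,
                reflect=config.langevin.g > 0,
            )
            censor = (
                rng.exponential(1.0 / config.censor_rate, size=n)
                if config.censor_rate > 0
                else np.full(n, np.inf)
            )
            ids = [f"{strain}-{sex}-{i:05d}" for i in range(n)]

            # assemble feature block per animal/visit where alive & uncensored
            for i in range(n):
                t_death = death_times[i]
                t_end = min(
                    t_death if np.isfinite(t_death) else np.inf,
                    censor[i],
                    horizon,
                )
                keep = ages < t_end
                if not keep.any():
                    continue  # no usable record; animal dropped entirely
                zi = z_visits[i, keep]
                vi = ages[keep]
                x = mu[None, :] + np.outer(zi, config.loadings)
                x = x + rng.standard_normal(x.shape) * config.feature_noise_sd
                if config.warp is not None:
                    x = config.warp(x, mu[None, :])
                mo = x[:, _I_WBC] - x[:, _I_LY] - x[:, _I_GR]
                mo_pct = 100.0 - x[:, _I_LYP] - x[:, _I_GRP]
                for k in range(vi.size):
                    row = {
                        "animal_id": ids[i],
                        "strain": strain,
                        "sex": sex,
                        "age_weeks": vi[k],
                        "GR%": x[k, 0], "GR": x[k, 1], "HB": x[k, 2],
                        "HCT%": x[k, 3], "LY%": x[k, 4], "LY": x[k, 5],
                        "MCHC": x[k, 6], "MCH": x[k, 7], "MCV": x[k, 8],
                        "PLT": x[k, 9], "RBC": x[k, 10], "WBC": x[k, 11],
                        "MO": mo[k], "MO%": mo_pct[k],
                    }
                    cohort_rows.append(row)
                    latent_rows.append(
                        {"animal_id": ids[i], "age_weeks": vi[k], "z_true": zi[k]}
                    )
                if np.isfinite(t_death) and t_death <= min(censor[i], horizon):
                    surv_rows.append(
                        {
                            "animal_id": ids[i],
                            "event_age_weeks": float(t_death),
                            "observed": 1,
                        }
                    )
                else:
                    surv_rows.append(
                        {
                            "animal_id": ids[i],
                            "event_age_weeks": float(min(censor[i], horizon)),
                            "observed": 0,
                        }
                    )

    cohort = pd.DataFrame(cohort_rows)
    drop = []
    if not config.emit_granulocytes:
        drop += ["GR", "GR%"]
    if not config.emit_monocytes:
        drop += ["MO", "MO%"]
    cols = [c for c in TABLE_COLUMNS if c not in drop]
    cohort = cohort[cols]
    survival = pd.DataFrame(surv_rows, columns=["animal_id", "event_age_weeks", "observed"])
    latent = pd.DataFrame(latent_rows, columns=["animal_id", "age_weeks", "z_true"])
    return cohort, survival, latent


def write_cohort(
    cohort: pd.DataFrame,
    survival: pd.DataFrame,
    config: CohortConfig,
    out_dir: str | Path,
) -> None:
    """Write cohort/survival CSVs plus a sidecar JSON with config and seed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.to_csv(out / "cohort.csv", index=False)
    survival.to_csv(out / "survival.csv", index=False)
    p = config.langevin
    meta = {
        "seed": config.seed,
        "n_per_strain_sex": config.n_per_strain_sex,
        "strains": [s for s, _ in config.strains],
        "visit_ages": list(map(float, config.visit_ages)),
        "langevin": {
            "alpha": p.alpha, "g": p.g,
            "noise_power": p.noise_power, "z_init": p.z_init,
        },
        "loadings": config.loadings.tolist(),
        "feature_noise_sd": config.feature_noise_sd.tolist(),
        "censor_rate": config.censor_rate,
        "emit_granulocytes": config.emit_granulocytes,
        "emit_monocytes": config.emit_monocytes,
    }
    (out / "config.json").write_text(json.dumps(meta, indent=2))
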