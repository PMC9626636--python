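"""One-dimensional stochastic model of organism-state instability.

The organism state is summarised by a scalar order parameter ``z`` obeying
the Langevin equation

    dz = (alpha * z + g * z**2) dt + sqrt(B) dW,

with ``alpha`` the (destabilising, when positive) stiffness, ``g`` the
lowest-order nonlinear coupling and ``B`` the power of the white noise.
For ``alpha > 0`` small deviations grow exponentially; once ``z`` exceeds
``Z = alpha / g`` the nonlinearity drives a finite-time blow-up, which we
identify with death.  The module provides an Euler--Maruyama simulator with
a blow-up death rule plus the closed-form mean, survival and hazard curves
of the linearised model.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.special import erf

__all__ = [
    "LangevinParams",
    "Trajectory",
    "SurvivalCurve",
    "HazardCurve",
    "simulate_trajectory",
    "simulate_cohort",
    "analytic_mean_z",
    "analytic_survival",
    "analytic_hazard",
    "mean_lifespan",
    "predicted_covariance",
]

#: z >= BLOWUP_FACTOR * Z is treated as divergence; the residual time to the
#: true blow-up from that point is < 1/(BLOWUP_FACTOR * alpha).
DEFAULT_BLOWUP_FACTOR = 10.0


def _rng(seed: int) -> np.random.Generator:
    """Counter-based generator used for every stochastic operation."""
    return np.random.Generator(np.random.Philox(seed))


@dataclass(frozen=True)
class LangevinParams:
    """Coefficients of the order-parameter equation.

    Parameters
    ----------
    alpha : float
        Stiffness, 1/week.  Positive values are dynamically unstable.
    g : float
        Nonlinear coupling, 1/(week * dFI-unit).  Must be >= 0.
    noise_power : float
        Power ``B`` of the white noise, dFI-unit^2/week.  Must be >= 0.
    z_init : float
        Initial value of the order parameter.
    """

    alpha: float
    g: float = 0.0
    noise_power: float = 0.0
    z_init: float = 0.0

    def __post_init__(self) -> None:
        vals = (self.alpha, self.g, self.noise_power, self.z_init)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("LangevinParams fields must be finite")
        if self.noise_power < 0:
            raise ValueError("noise_power must be >= 0")
        if self.g < 0:
            raise ValueError("g must be >= 0")

    @property
    def Z(self) -> float:
        """Blow-up scale alpha/g (defined for alpha > 0, g > 0)."""
        if self.alpha <= 0 or self.g <= 0:
            raise ValueError("Z = alpha/g requires alpha > 0 and g > 0")
        return self.alpha / self.g

    @property
    def z_bar(self) -> float:
        """Noise-driven amplitude sqrt(B / (2 alpha)) (alpha > 0)."""
        if self.alpha <= 0:
            raise ValueError("z_bar requires alpha > 0")
        return math.sqrt(self.noise_power / (2.0 * self.alpha))

    @property
    def t_bar(self) -> float:
        """Mean lifespan ln(Z/z_bar)/alpha (requires Z > z_bar)."""
        zb = self.z_bar
        Z = self.Z
        if not Z > zb:
            raise ValueError("t_bar requires Z > z_bar")
        return math.log(Z / zb) / self.alpha


@dataclass
class Trajectory:
    """A single simulated path of the order parameter."""

    times: np.ndarray
    z: np.ndarray
    death_time: Optional[float] = None
    death_cause: str = "none"  # "blow-up" | "none"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if self.times.size != self.z.size:
            raise ValueError("times and z must have equal length")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.z)):
            raise ValueError("z must be finite at all recorded times")
        if self.death_time is not None and self.times.size:
            if self.times[-1] > self.death_time:
                raise ValueError("no z may be recorded after death_time")

    def to_frame(self, animal_id: str = "a0"):
        import pandas as pd

        return pd.DataFrame(
            {"animal_id": animal_id, "time_weeks": self.times, "z": self.z}
        )


@dataclass
class SurvivalCurve:
    """Fraction surviving as a function of age."""

    times: np.ndarray
    survival: np.ndarray
    ci_low: Optional[np.ndarray] = None
    ci_high: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.survival = np.asarray(self.survival, dtype=float)
        if np.any(self.survival > 1 + 1e-12) or np.any(self.survival < -1e-12):
            raise ValueError("survival must lie in [0, 1]")
        if np.any(np.diff(self.survival) > 1e-12):
            raise ValueError("survival must be non-increasing")


@dataclass
class HazardCurve:
    """Hazard (1/week) and cumulative hazard versus age."""

    times: np.ndarray
    hazard: np.ndarray
    cumhaz: np.ndarray
    ci_low: Optional[np.ndarray] = None
    ci_high: Optional[np.ndarray] = None
    at_risk: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.hazard = np.asarray(self.hazard, dtype=float)
        self.cumhaz = np.asarray(self.cumhaz, dtype=float)
        if np.any(self.hazard < -1e-12):
            raise ValueError("hazard must be >= 0")
        if np.any(np.diff(self.cumhaz) < -1e-9):
            raise ValueError("cumulative hazard must be non-decreasing")


def _check_step(params: LangevinParams, step: float) -> None:
    if step <= 0:
        raise ValueError("step must be > 0")
    if abs(params.alpha) * step > 0.1:
        warnings.warn(
            f"step {step} too large for stability (step*alpha = "
            f"{abs(params.alpha) * step:.3g} > 0.1)",
            RuntimeWarning,
            stacklevel=3,
        )


def simulate_trajectory(
    params: LangevinParams,
    horizon: float,
    step: float = 0.01,
    seed: int = 0,
    blowup_factor: float = DEFAULT_BLOWUP_FACTOR,
    reflect: bool = True,
) -> Trajectory:
    """Euler--Maruyama integration of a single order-parameter path.

    Death is recorded the first time ``z`` reaches ``blowup_factor * Z``
    (only meaningful when ``alpha > 0`` and ``g > 0``); the path is
    truncated at that instant.

    ``reflect`` keeps the path non-negative by folding at zero.  Without
    it the quadratic drift has a stable fixed point at ``-Z`` that traps a
    macroscopic fraction of paths forever; the folded process corresponds
    to the two-sided threshold behind the closed-form Erf survival.  Pass
    ``reflect=False`` to study the free linear process (e.g. to verify
    Gaussian moments when ``g = 0``).
    """
    if horizon <= 0:
        raise ValueError("horizon must be > 0")
    _check_step(params, step)
    rng = _rng(seed)

    n_steps = int(round(horizon / step))
    times = np.empty(n_steps + 1)
    zs = np.empty(n_steps + 1)
    times[0] = 0.0
    zs[0] = params.z_init

    guard = np.inf
    if params.g > 0 and params.alpha > 0:
        guard = blowup_factor * params.Z

    sqrt_b_dt = math.sqrt(params.noise_power * step)
    z = params.z_init
    death_time = None
    n_kept = n_steps + 1
    for k in range(1, n_steps + 1):
        drift = params.alpha * z + params.g * z * z
        z = z + drift * step
        if sqrt_b_dt:
            z += sqrt_b_dt * rng.standard_normal()
        if reflect and z < 0:
            z = -z
        t = k * step
        if z >= guard:
            death_time = t
            n_kept = k  # drop the diverging point itself
            break
        times[k] = t
        zs[k] = z

    traj = Trajectory(
        times=times[:n_kept],
        z=zs[:n_kept],
        death_time=death_time,
        death_cause="blow-up" if death_time is not None else "none",
    )
    return traj


def simulate_cohort(
    params: LangevinParams,
    n: int,
    horizon: float,
    step: float = 0.01,
    seed: int = 0,
    visit_ages: Optional[np.ndarray] = None,
    blowup_factor: float = DEFAULT_BLOWUP_FACTOR,
    reflect: bool = True,
) -> tuple[np.ndarray, Optional[np.ndarray]]:
    """Vectorised simulation of ``n`` independent paths.

    See :func:`simulate_trajectory` for the death rule and the meaning of
    ``reflect``.

    Returns
    -------
    death_times : (n,) array
        Blow-up times; ``nan`` for animals alive at the horizon.
    z_at_visits : (n, len(visit_ages)) array or None
        Latent values sampled at the requested ages (``nan`` after death).
    """
    if n <= 0:
        raise ValueError("n must be > 0")
    if horizon <= 0:
        raise ValueError("horizon must be > 0")
    _check_step(params, step)
    rng = _rng(seed)

    guard = np.inf
    if params.g > 0 and params.alpha > 0:
        guard = blowup_factor * params.Z

    visit_idx = None
    z_at_visits = None
    if visit_ages is not None:
        visit_ages = np.asarray(visit_ages, dtype=float)
        visit_idx = np.rint(visit_ages / step).astype(int)
        z_at_visits = np.full((n, visit_ages.size), np.nan)

    n_steps = int(round(horizon / step))
    z = np.full(n, params.z_init)
    alive = np.ones(n, dtype=bool)
    death_times = np.full(n, np.nan)
    sqrt_b_dt = math.sqrt(params.noise_power * step)

    if visit_idx is not None:
        at0 = np.nonzero(visit_idx == 0)[0]
        for j in at0:
            z_at_visits[:, j] = z

    for k in range(1, n_steps + 1):
        idx = np.nonzero(alive)[0]
        if idx.size == 0:
            break
        zi = z[idx]
        zi = zi + (params.alpha * zi + params.g * zi * zi) * step
        if sqrt_b_dt:
            zi += sqrt_b_dt * rng.standard_normal(idx.size)
        if reflect:
            np.abs(zi, out=zi)
        died = zi >= guard
        if died.any():
            dead_ids = idx[died]
            death_times[dead_ids] = k * step
            alive[dead_ids] = False
        z[idx] = zi
        if visit_idx is not None:
            hits = np.nonzero(visit_idx == k)[0]
            for j in hits:
                live = alive
                z_at_visits[live, j] = z[live]

    return death_times, z_at_visits


def analytic_mean_z(
    params: LangevinParams, z_bar_fit: float, z0: float, t
):
    """Late-life mean path ``z_bar * exp(alpha t) + z0`` of the linear model."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    if not (np.isfinite(z_bar_fit) and np.isfinite(z0)):
        raise ValueError("non-finite inputs")
    out = z_bar_fit * np.exp(params.alpha * t) + z0
    return float(out) if out.ndim == 0 else out


def analytic_survival(params: LangevinParams, ratio: float, t):
    """Closed-form survival ``Erf(ratio * exp(-alpha t))``.

    ``ratio`` is the dimensionless scale ``Z / z_bar``; treated as a fit
    parameter when comparing to simulations.
    """
    if not ratio > 0:
        raise ValueError("ratio must be > 0")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    out = erf(ratio * np.exp(-params.alpha * t))
    return float(out) if out.ndim == 0 else out


def analytic_hazard(params: LangevinParams, ratio: float, t):
    """Hazard ``-S'/S`` of the closed-form survival.

    With ``u = ratio * exp(-alpha t)``:

        M(t) = (2/sqrt(pi)) * alpha * u * exp(-u^2) / Erf(u)

    which increases monotonically to the plateau ``alpha`` as ``u -> 0``.
    """
    if not ratio > 0:
        raise ValueError("ratio must be > 0")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    u = ratio * np.exp(-params.alpha * t)
    u = np.atleast_1d(u)
    out = np.empty_like(u)
    small = u < 1e-6
    # series: Erf(u) = 2/sqrt(pi) (u - u^3/3 + ...)
    out[small] = params.alpha * (1.0 - 2.0 * u[small] ** 2 / 3.0)
    ub = u[~small]
    out[~small] = (
        2.0 / math.sqrt(math.pi) * params.alpha * ub * np.exp(-(ub**2)) / erf(ub)
    )
    if np.ndim(t) == 0:
        return float(out[0])
    return out


def mean_lifespan(params: LangevinParams, ratio: float) -> float:
    """Mean lifespan ``ln(ratio) / alpha`` of the blow-up model."""
    if not ratio > 1:
        raise ValueError("ratio must be > 1 for a positive lifespan")
    if not params.alpha > 0:
        raise ValueError("alpha must be > 0")
    return math.log(ratio) / params.alpha


def predicted_covariance(
    loadings: np.ndarray, params: LangevinParams, t: float
) -> np.ndarray:
    """Rank-1 feature covariance ``b_i b_j (B / 2 alpha) exp(2 alpha t)``."""
    if not params.alpha > 0:
        raise ValueError("alpha must be > 0")
    b = np.asarray(loadings, dtype=float)
    amp = params.noise_power / (2.0 * params.alpha) * math.exp(
        2.0 * params.alpha * t
    )
    return amp * np.outer(b, b)


def riccati_blowup_time(params: LangevinParams, z0: float) -> float:
    """Closed-form blow-up time of the noiseless equation from ``z0 > 0``.

    Solving dz/dt = alpha z + g z^2 gives divergence at
    ``(1/alpha) ln(1 + Z/z0)``; used as an independent oracle for the
    simulator's death rule.
    """
    if z0 <= 0:
        raise ValueError("z0 must be > 0")
    return math.log(1.0 + params.Z / z0) / params.alpha
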