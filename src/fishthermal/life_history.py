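"""Growth through ontogeny, survival and lifetime fitness.

Surplus energy is split between somatic growth and reproduction by a
logistic maturation reaction norm (MRN),

    psi(w) = 1 / (1 + exp(-c_mrn (w - w*)))

so weight grows as dw/dt = (1 - psi) P(w, T, tau*) with the activity
fraction tau* re-optimized (Gilliam's rule under the oxygen constraint) as
the fish grows.  Survival follows the hazard of the realized mortality,
S(t) = exp(-int_0^t M ds), and lifetime reproductive output is

    R0 = int_0^inf psi(w(t)) P(w(t), T, tau*) S(t) dt

in units of survival-weighted grams allocated to reproduction (no egg-size
normalization: only relative R0 across conditions is meaningful).  Negative
instantaneous contributions are clipped to zero in the R0 integrand
(starving fish do not produce negative offspring), while weight itself may
shrink down to a floor.

The reaction-norm intercept w* is a fixed evolved trait: it is calibrated by
maximizing R0 at the reference temperature (15 degC) and baseline food, then
held fixed as temperature changes.

Re-optimizing activity inside the ODE right-hand side is the dominant cost,
so tau*(w) is precomputed on a log-spaced weight grid and monotone-cubically
interpolated (:class:`TauStarCache`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq, minimize_scalar

from .behaviour import optimal_activity
from .bioenergetics import energy_gain, mortality
from .params import MRNParams, ParameterBundle

__all__ = [
    "allocation",
    "TauStarCache",
    "asymptotic_weight_bound",
    "GrowthTrajectory",
    "grow",
    "grow_to_plateau",
    "FitnessResult",
    "lifetime_fitness",
    "CalibrationResult",
    "calibrate_wstar",
]


def allocation(w, mrn: MRNParams, t=0.0):
    """Fraction of surplus energy allocated to reproduction, psi in [0, 1].

    Flat reaction norm (slope = 0): a logistic in weight with midpoint
    ``w_star`` and steepness ``c_mrn``.  A non-zero slope shifts the midpoint
    linearly with age: ``w_star + slope * t``.
    """
    midpoint = mrn.w_star + mrn.slope * np.asarray(t, dtype=float)
    z = -mrn.c_mrn * (np.asarray(w, dtype=float) - midpoint)
    out = 1.0 / (1.0 + np.exp(np.clip(z, -700.0, 700.0)))
    return out if out.ndim else float(out)


def _max_energy_gain(w: float, T: float, bundle: ParameterBundle,
                     food: float) -> float:
    """max over tau in [0, 1] of P(w, T, tau), ignoring oxygen."""
    grid = np.linspace(0.0, 1.0, 513)
    return float(np.max(energy_gain(w, T, grid, bundle.traits, bundle.thermal, food)))


def asymptotic_weight_bound(bundle: ParameterBundle, T: float,
                            food: float = 1.0) -> float:
    """Weight at which even the energy-maximizing activity just breaks even.

    The root of max_tau P(w, T, tau) = 0: an upper bound on any attainable
    weight at (T, food), used to size weight grids.  Returns the integration
    floor if no growth is possible at all.
    """
    lo = bundle.sim.w_floor
    if _max_energy_gain(lo, T, bundle, food) <= 0.0:
        return lo
    hi = max(10.0 * lo, 10.0)
    while _max_energy_gain(hi, T, bundle, food) > 0.0:
        hi *= 4.0
        if hi > 1e9:  # costs ~ w always overtake intake ~ w^q eventually
            raise RuntimeError("no asymptotic weight below 1e9 g")
    return float(brentq(lambda w: _max_energy_gain(w, T, bundle, food), lo, hi,
                        xtol=1e-8, rtol=1e-10))


class TauStarCache:
    """Realized activity tau*(w) at fixed (T, food), interpolated over weight.

    Solves the constrained activity optimization on ``sim.cache_points``
    log-spaced weights spanning the floor to just above the asymptotic
    bound, then interpolates tau* monotone-cubically in log weight.
    Resting-metabolism feasibility does not depend on weight (supply and
    resting demand both scale as w^n), so a single flag covers the grid.
    """

    def __init__(self, bundle: ParameterBundle, T: float, food: float = 1.0,
                 w_hi: float | None = None):
        self.bundle = bundle
        self.T = float(T)
        self.food = float(food)
        sim = bundle.sim
        if w_hi is None:
            w_hi = max(asymptotic_weight_bound(bundle, T, food) * 1.1,
                       10.0 * sim.w0)
        self.w_hi = float(w_hi)
        self.w_grid = np.geomspace(sim.w_floor, self.w_hi, sim.cache_points)
        solutions = [optimal_activity(w, T, bundle, food) for w in self.w_grid]
        self.feasible = solutions[0].feasible
        self.tau_grid = np.array([s.tau_star for s in solutions])
        self.limited = np.array([s.limited_by_oxygen for s in solutions])
        self._interp = PchipInterpolator(np.log(self.w_grid), self.tau_grid,
                                         extrapolate=False)

    def __call__(self, w):
        logw = np.log(np.clip(w, self.w_grid[0], self.w_grid[-1]))
        out = np.clip(self._interp(logw), 0.0, 1.0)
        return out if np.ndim(w) else float(out)


@dataclass(frozen=True)
class GrowthTrajectory:
    """A growth, survival and reproduction trajectory at fixed (T, food)."""

    t: np.ndarray  # ages, y
    w: np.ndarray  # weights, g
    L: np.ndarray  # lengths, cm (w = condition_factor * L^3)
    tau_star: np.ndarray  # realized activity
    psi: np.ndarray  # allocation to reproduction
    M: np.ndarray  # mortality rate, y⁻¹
    S: np.ndarray  # cumulative survival
    R: np.ndarray  # cumulative survival-weighted reproductive output, g
    T: float
    food: float
    w_star_used: float
    feasible: bool  # resting metabolism oxygen-feasible at this T

    @property
    def maturation_age(self) -> float | None:
        """Age at 50% allocation to reproduction (linear interpolation)."""
        above = self.psi >= 0.5
        if not above.any() or above[0]:
            return float(self.t[0]) if above.any() else None
        i = int(np.argmax(above))
        t0, t1 = self.t[i - 1], self.t[i]
        p0, p1 = self.psi[i - 1], self.psi[i]
        return float(t0 + (0.5 - p0) * (t1 - t0) / (p1 - p0))

    @property
    def R0(self) -> float:
        return float(self.R[-1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t": self.t, "w": self.w, "L": self.L, "tau_star": self.tau_star,
            "psi": self.psi, "M": self.M, "S": self.S, "R": self.R,
        })


def _integrate(bundle: ParameterBundle, T: float, food: float, w_star: float,
               cache: TauStarCache, horizon: float, n_out: int) -> GrowthTrajectory:
    sim = bundle.sim
    traits, thermal = bundle.traits, bundle.thermal
    mrn = bundle.mrn if w_star is None else MRNParams(
        w_star=w_star, c_mrn=bundle.mrn.c_mrn, slope=bundle.mrn.slope)
    t_eval = np.linspace(0.0, horizon, n_out)

    if not cache.feasible:
        # Even resting metabolism cannot be sustained: immediate death.
        w = np.full_like(t_eval, sim.w0)
        S = np.zeros_like(t_eval)
        S[0] = 1.0
        zeros = np.zeros_like(t_eval)
        return GrowthTrajectory(
            t=t_eval, w=w, L=np.cbrt(w / sim.condition_factor),
            tau_star=zeros, psi=allocation(w, mrn, t_eval),
            M=mortality(w, zeros, traits), S=S, R=zeros,
            T=T, food=food, w_star_used=float(mrn.w_star), feasible=False,
        )

    floor = sim.w_floor

    def rhs(t: float, y: np.ndarray) -> list[float]:
        w = min(max(y[0], floor), cache.w_hi)
        tau = cache(w)
        P = energy_gain(w, T, tau, traits, thermal, food)
        psi = allocation(w, mrn, t)
        dw = (1.0 - psi) * P
        if y[0] <= floor and dw < 0.0:
            dw = 0.0
        M = mortality(w, tau, traits)
        survival = np.exp(-min(y[1], 700.0))
        dR = psi * max(P, 0.0) * survival
        return [dw, M, dR]

    sol = solve_ivp(rhs, (0.0, horizon), [sim.w0, 0.0, 0.0], t_eval=t_eval,
                    method="RK45", rtol=sim.ode_rtol, atol=1e-10)
    if not sol.success:  # pragma: no cover - defensive
        raise RuntimeError(f"growth integration failed: {sol.message}")
    w = np.clip(sol.y[0], floor, cache.w_hi)
    tau = cache(w)
    return GrowthTrajectory(
        t=t_eval, w=w, L=np.cbrt(w / sim.condition_factor),
        tau_star=tau, psi=allocation(w, mrn, t_eval),
        M=mortality(w, tau, traits), S=np.exp(-sol.y[1]), R=sol.y[2],
        T=T, food=food, w_star_used=float(mrn.w_star), feasible=True,
    )


def grow(bundle: ParameterBundle, T: float, food: float = 1.0,
         w_star: float | None = None, horizon: float | None = None,
         n_out: int = 201, cache: TauStarCache | None = None) -> GrowthTrajectory:
    """Integrate growth, survival and reproduction from ``sim.w0``.

    ``w_star`` overrides the bundle's reaction-norm intercept (pass the
    calibrated value); ``cache`` allows reusing a precomputed
    :class:`TauStarCache` for this (T, food).
    """
    if cache is None:
        cache = TauStarCache(bundle, T, food)
    if horizon is None:
        horizon = bundle.sim.t_horizon
    if w_star is None:
        w_star = bundle.mrn.w_star
    return _integrate(bundle, T, food, w_star, cache, horizon, n_out)


def grow_to_plateau(bundle: ParameterBundle, T: float, food: float = 1.0,
                    w_star: float | None = None, rel_tol: float = 1e-4,
                    max_horizon: float = 800.0,
                    cache: TauStarCache | None = None) -> GrowthTrajectory:
    """Integrate until the weight change per year falls below ``rel_tol``.

    Doubles the horizon (starting from ``sim.t_horizon``) until the relative
    weight change over the final year is below ``rel_tol`` or ``max_horizon``
    is reached.
    """
    if cache is None:
        cache = TauStarCache(bundle, T, food)
    horizon = bundle.sim.t_horizon
    while True:
        n_out = max(201, int(horizon) + 1)
        traj = grow(bundle, T, food, w_star, horizon, n_out, cache)
        if not traj.feasible:
            return traj
        w_prev = float(np.interp(horizon - 1.0, traj.t, traj.w))
        if abs(traj.w[-1] - w_prev) <= rel_tol * traj.w[-1]:
            return traj
        if horizon >= max_horizon:
            return traj
        horizon = min(2.0 * horizon, max_horizon)


@dataclass(frozen=True)
class FitnessResult:
    """Lifetime reproductive output at one temperature."""

    R0: float  # survival-weighted reproductive output, g
    T: float
    food: float
    w_star_used: float
    converged: bool  # integrand decayed within the horizon
    feasible: bool


def lifetime_fitness(bundle: ParameterBundle, T: float, food: float = 1.0,
                     w_star: float | None = None,
                     cache: TauStarCache | None = None) -> FitnessResult:
    """Compute R0 at (T, food) for a given reaction-norm intercept."""
    traj = grow(bundle, T, food, w_star, cache=cache)
    if not traj.feasible:
        return FitnessResult(R0=0.0, T=float(T), food=float(food),
                             w_star_used=traj.w_star_used,
                             converged=True, feasible=False)
    R0 = traj.R0
    if R0 > 0.0:
        i_tail = int(np.searchsorted(traj.t, 0.9 * traj.t[-1]))
        converged = (R0 - traj.R[min(i_tail, len(traj.R) - 1)]) <= 1e-3 * R0
    else:
        converged = True
    return FitnessResult(R0=R0, T=float(T), food=float(food),
                         w_star_used=traj.w_star_used,
                         converged=bool(converged), feasible=True)


@dataclass(frozen=True)
class CalibrationResult:
    """Calibrated reaction-norm intercept."""

    w_star: float  # g
    R0: float  # fitness at the calibrated intercept
    T: float
    food: float
    flat_objective: bool  # fitness surface flat to tolerance; smallest w* kept


def calibrate_wstar(bundle: ParameterBundle, T: float | None = None,
                    food: float = 1.0) -> CalibrationResult:
    """Find the reaction-norm intercept maximizing R0.

    Performed at the reference temperature (``thermal.T0``, 15 degC by
    default) and baseline food; the result is then held fixed as conditions
    change.  Log-spaced grid scan over [1 g, asymptotic bound] refined by
    bounded golden-section search; deterministic, so recalibration is
    idempotent.
    """
    if T is None:
        T = bundle.thermal.T0
    sim = bundle.sim
    cache = TauStarCache(bundle, T, food)

    def r0(w_star: float) -> float:
        return lifetime_fitness(bundle, T, food, w_star, cache=cache).R0

    w_hi = max(asymptotic_weight_bound(bundle, T, food), 2.0)
    grid = np.geomspace(1.0, w_hi, sim.wstar_grid_points)
    values = np.array([r0(w) for w in grid])
    idx = int(np.argmax(values))
    flat = bool(np.ptp(values) <= 1e-12 * max(1.0, abs(values[idx])))
    lo = grid[max(idx - 1, 0)]
    hi = grid[min(idx + 1, len(grid) - 1)]
    best_w, best_v = float(grid[idx]), float(values[idx])
    if not flat and hi > lo:
        res = minimize_scalar(lambda lw: -r0(float(np.exp(lw))),
                              bounds=(np.log(lo), np.log(hi)), method="bounded",
                              options={"xatol": np.log1p(sim.wstar_rel_tol)})
        w_ref, v_ref = float(np.exp(res.x)), float(-res.fun)
        if v_ref > best_v:
            best_w, best_v = w_ref, v_ref
    return CalibrationResult(w_star=best_w, R0=best_v, T=float(T),
                             food=float(food), flat_objective=flat)
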