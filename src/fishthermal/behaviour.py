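"""Optimal activity allocation under the aerobic-scope constraint.

Fish adjust the fraction of time spent actively foraging, tau in [0, 1], to
maximize net energy gain over mortality (Gilliam's rule),

    tau* = argmax_tau P(w, T, tau) / M(w, tau),

subject to the oxygen feasibility constraint P_O2(tau) >= 0: on the
timescales modelled, the aerobic scope may not go negative (no oxygen debt
or anaerobic metabolism).  Three diagnostic activity levels are exposed: the
unconstrained optimum, the maximum oxygen-feasible activity, and the
realized activity (their minimum).

The optimizer is a deterministic dense-grid scan refined by bounded
golden-section search, so results are bit-reproducible.  When no feasible
activity yields a positive energy gain, the fish minimizes its losses:
tau* maximizes P itself (maximizing the negative ratio P/M would reward high
mortality).  Flat stretches of the objective resolve to the smallest tau
(risk-averse tie-break).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, minimize_scalar

from .bioenergetics import energy_gain, mortality, oxygen_budget
from .params import ParameterBundle

__all__ = ["ActivitySolution", "max_activity", "optimal_activity"]


@dataclass(frozen=True)
class ActivitySolution:
    """Solution of the constrained activity optimization at one (w, T)."""

    tau_opt_unconstrained: float  # argmax of the objective ignoring oxygen
    tau_max: float  # largest oxygen-feasible tau (0 if none)
    tau_star: float  # realized activity
    limited_by_oxygen: bool  # oxygen constrains the realized activity
    feasible: bool  # resting metabolism is oxygen-feasible
    objective_value: float  # P/M at tau_star
    P: float  # net energy gain at tau_star, g·y⁻¹
    M: float  # mortality at tau_star, y⁻¹
    P_O2: float  # aerobic scope at tau_star, O2-mass·y⁻¹


def max_activity(w: float, T: float, bundle: ParameterBundle,
                 food: float = 1.0) -> tuple[float, bool]:
    """Largest tau in [0, 1] with non-negative aerobic scope.

    P_O2 is strictly decreasing in tau, so the boundary is the unique root
    of P_O2(tau) = 0.  Returns ``(tau_max, feasible)``; ``feasible`` is False
    when even resting metabolism (tau = 0) cannot be sustained, in which case
    tau_max is 0.
    """
    traits, thermal = bundle.traits, bundle.thermal

    def scope(tau: float) -> float:
        return oxygen_budget(w, T, tau, traits, thermal, food)[2]

    if scope(0.0) < 0.0:
        return 0.0, False
    if scope(1.0) >= 0.0:
        return 1.0, True
    root = brentq(scope, 0.0, 1.0, xtol=bundle.sim.root_tol)
    return float(root), True


def _refine(objective, lo: float, hi: float, tau_grid_best: float,
            best_value: float, xatol: float) -> tuple[float, float]:
    """Bounded golden-section refinement around a grid argmax.

    Keeps the grid point on ties or if refinement does not improve
    (smallest-tau tie-break).
    """
    if hi <= lo:
        return tau_grid_best, best_value
    res = minimize_scalar(lambda t: -objective(t), bounds=(lo, hi),
                          method="bounded", options={"xatol": xatol})
    tau_ref, val_ref = float(res.x), float(-res.fun)
    if val_ref > best_value + abs(best_value) * 1e-13:
        return tau_ref, val_ref
    return tau_grid_best, best_value


def optimal_activity(w: float, T: float, bundle: ParameterBundle,
                     food: float = 1.0) -> ActivitySolution:
    """Solve the constrained Gilliam's-rule optimization at one (w, T)."""
    traits, thermal, sim = bundle.traits, bundle.thermal, bundle.sim
    tau_max, feasible = max_activity(w, T, bundle, food)

    grid = np.linspace(0.0, 1.0, sim.tau_grid_points)
    P_grid = energy_gain(w, T, grid, traits, thermal, food)
    M_grid = mortality(w, grid, traits)

    def P_of(tau: float) -> float:
        return energy_gain(w, T, tau, traits, thermal, food)

    def ratio_of(tau: float) -> float:
        return P_of(tau) / mortality(w, tau, traits)

    step = grid[1] - grid[0]

    def argmax_refined(objective, values: np.ndarray, upper: float) -> float:
        mask = grid <= upper + 1e-15
        idx = int(np.argmax(values[mask]))
        lo = max(0.0, grid[idx] - step)
        hi = min(upper, grid[idx] + step)
        tau_best, _ = _refine(objective, lo, hi, float(grid[idx]),
                              float(values[mask][idx]), sim.tau_tol)
        return min(tau_best, upper)

    # Unconstrained optimum over [0, 1]: Gilliam ratio when some tau earns a
    # positive gain, otherwise loss minimization (argmax P).
    if np.max(P_grid) > 0.0:
        tau_opt = argmax_refined(ratio_of, P_grid / M_grid, 1.0)
    else:
        tau_opt = argmax_refined(P_of, P_grid, 1.0)

    if not feasible:
        tau_star = 0.0
        limited = True
    else:
        feasible_P = P_grid[grid <= tau_max + 1e-15]
        if np.max(feasible_P) > 0.0:
            tau_star = min(tau_opt, tau_max)
        else:
            # No feasible activity earns energy: minimize the loss.
            tau_star = argmax_refined(P_of, P_grid, tau_max)
        limited = tau_opt > tau_max

    P_star = P_of(tau_star)
    M_star = mortality(w, tau_star, traits)
    scope_star = oxygen_budget(w, T, tau_star, traits, thermal, food)[2]
    return ActivitySolution(
        tau_opt_unconstrained=float(tau_opt),
        tau_max=float(tau_max),
        tau_star=float(tau_star),
        limited_by_oxygen=bool(limited),
        feasible=bool(feasible),
        objective_value=float(P_star / M_star),
        P=float(P_star),
        M=float(M_star),
        P_O2=float(scope_star),
    )
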