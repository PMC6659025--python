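"""Instantaneous rates at a given (weight, temperature, activity).

The energy budget is net energy gain P = supply - demand,

    P(w, T, tau) = (1 - beta - phi_e) f h c(T) w^q - c(T) k w^n - tau c(T) k_a w

with f the Holling type-II feeding level.  The oxygen budget (aerobic scope)
has the same shape: supply S_O2(T) w^n against the oxygen cost of SDA,
standard and active metabolism.  Mortality rises with the activity fraction,
M = (rho + mu tau) w^(q-1).

``food`` scales the encountered-food coefficient gamma_theta (the baseline
resource level corresponds to food=1; the packaged scenarios also use 2/3
and 4/3).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ParameterBundle, ThermalOxygenParams, TraitParams
from .thermal import arrhenius_factor, oxygen_supply_coeff

__all__ = [
    "BudgetState",
    "feeding_level",
    "max_consumption",
    "energy_gain",
    "oxygen_budget",
    "mortality",
    "budget_state",
]


def max_consumption(w, T, traits: TraitParams, thermal: ThermalOxygenParams):
    """Maximum consumption rate h c(T) w^q (g·y⁻¹)."""
    return traits.h * arrhenius_factor(T, thermal) * np.power(w, traits.q)


def feeding_level(w, T, tau, traits: TraitParams, thermal: ThermalOxygenParams,
                  food: float = 1.0):
    """Holling type-II feeding level f in [0, 1].

    f = tau gamma_theta w^p / (tau gamma_theta w^p + h c(T) w^q): encountered
    food (activity fraction times clearance rate times resource availability)
    saturated by the maximum consumption rate.
    """
    encountered = np.asarray(tau, dtype=float) * food * traits.gamma_theta \
        * np.power(w, traits.p)
    out = np.where(
        encountered > 0.0,
        encountered / (encountered + max_consumption(w, T, traits, thermal)),
        0.0,
    )
    return out if out.ndim else float(out)


def energy_gain(w, T, tau, traits: TraitParams, thermal: ThermalOxygenParams,
                food: float = 1.0):
    """Net energy gain P (g·y⁻¹): assimilated intake minus metabolic costs.

    Intake is discounted by SDA (beta) and egestion/excretion (phi_e);
    standard metabolism k w^n and active metabolism tau k_a w both carry the
    Arrhenius factor c(T).
    """
    c = arrhenius_factor(T, thermal)
    f = feeding_level(w, T, tau, traits, thermal, food)
    w = np.asarray(w, dtype=float)
    supply = (1.0 - traits.beta - traits.phi_e) * f * traits.h * c * np.power(w, traits.q)
    demand = c * traits.k * np.power(w, traits.n) \
        + np.asarray(tau, dtype=float) * c * traits.k_a * w
    out = supply - demand
    return out if out.ndim else float(out)


def oxygen_budget(w, T, tau, traits: TraitParams, thermal: ThermalOxygenParams,
                  food: float = 1.0, strict_paper: bool = False):
    """Oxygen demand, supply and aerobic scope (O2-mass·y⁻¹).

    Demand is the oxygen cost of SDA, standard and active metabolism,

        D_O2 = omega c(T) (beta f h w^q + k w^n + tau k_a w)

    supply is S_O2w = S_O2(T) w^n, and the aerobic scope is
    P_O2 = S_O2w - D_O2.  With ``strict_paper`` the active term is the
    maximal-demand form k_a w (no tau), so the demand no longer depends on
    the realized activity; both forms coincide at tau = 1.

    Returns
    -------
    (D_O2, S_O2w, P_O2)
    """
    c = arrhenius_factor(T, thermal)
    f = feeding_level(w, T, tau, traits, thermal, food)
    w = np.asarray(w, dtype=float)
    active_fraction = 1.0 if strict_paper else np.asarray(tau, dtype=float)
    demand = thermal.omega * c * (
        traits.beta * f * traits.h * np.power(w, traits.q)
        + traits.k * np.power(w, traits.n)
        + active_fraction * traits.k_a * w
    )
    supply = oxygen_supply_coeff(T, thermal) * np.power(w, traits.n)
    scope = supply - demand
    if np.ndim(scope):
        return demand, supply, scope
    return float(demand), float(supply), float(scope)


def mortality(w, tau, traits: TraitParams):
    """Mortality rate M = (rho + mu tau) w^(q-1) (y⁻¹)."""
    out = (traits.rho + traits.mu * np.asarray(tau, dtype=float)) \
        * np.power(np.asarray(w, dtype=float), traits.q - 1.0)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class BudgetState:
    """All instantaneous rates at one (w, T, tau) point."""

    w: float  # weight, g
    T: float  # temperature, degC
    tau: float  # activity fraction
    f: float  # feeding level
    intake: float  # realized consumption f h c(T) w^q, g·y⁻¹
    P: float  # net energy gain, g·y⁻¹
    D_O2: float  # oxygen demand, O2-mass·y⁻¹
    S_O2w: float  # oxygen supply S_O2(T) w^n, O2-mass·y⁻¹
    P_O2: float  # aerobic scope, O2-mass·y⁻¹
    M: float  # mortality rate, y⁻¹


def budget_state(w: float, T: float, tau: float, bundle: ParameterBundle,
                 food: float = 1.0) -> BudgetState:
    """Evaluate the full budget at one point."""
    traits, thermal = bundle.traits, bundle.thermal
    f = feeding_level(w, T, tau, traits, thermal, food)
    demand, supply, scope = oxygen_budget(w, T, tau, traits, thermal, food)
    return BudgetState(
        w=float(w),
        T=float(T),
        tau=float(tau),
        f=float(f),
        intake=float(f * max_consumption(w, T, traits, thermal)),
        P=float(energy_gain(w, T, tau, traits, thermal, food)),
        D_O2=demand,
        S_O2w=supply,
        P_O2=scope,
        M=float(mortality(w, tau, traits)),
    )
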