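"""Performance metrics and factorial scenario sweeps.

Four performance measures with different ecological readings:

* growth curves through ontogeny (see :mod:`fishthermal.life_history`),
* production efficiency — surplus energy per unit food consumed,
  P / (f h c(T) w^q), bounded above by the assimilation fraction
  1 - beta - phi_e,
* the dimensionless Gilliam ratio P / (M w), the short-sighted fitness proxy,
* lifetime reproductive output R0.

:func:`run_sweep` evaluates these over the factorial design
(strategy x MOS regime x temperature x food x size) and returns a tidy
table; "relative to maximum" normalizations are computed within each
(strategy, mos_regime, food) group, matching the per-panel scope of the
scenario figures this sweep reproduces.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import params as _params
from .behaviour import optimal_activity
from .bioenergetics import energy_gain, feeding_level, max_consumption, mortality
from .life_history import TauStarCache, calibrate_wstar, grow_to_plateau, lifetime_fitness
from .params import ParameterBundle, ThermalOxygenParams, TraitParams, preset

__all__ = [
    "production_efficiency",
    "gilliam_ratio",
    "run_sweep",
    "write_csv",
]

#: The diagnostic weights (g) used throughout the scenario figures:
#: 5, 10 and 20 cm fish under the default condition factor.
DEFAULT_SIZES = (1.25, 10.0, 80.0)


def production_efficiency(w, T, tau, traits: TraitParams,
                          thermal: ThermalOxygenParams, food: float = 1.0):
    """Surplus energy per unit food consumed, P / (f h c(T) w^q).

    Undefined (NaN) where the feeding level is zero (tau = 0).  Always below
    the assimilation fraction 1 - beta - phi_e, since metabolic costs only
    subtract from assimilated intake.
    """
    f = feeding_level(w, T, tau, traits, thermal, food)
    consumption = f * max_consumption(w, T, traits, thermal)
    P = energy_gain(w, T, tau, traits, thermal, food)
    out = np.where(consumption > 0.0, P / np.where(consumption > 0.0, consumption, 1.0),
                   np.nan)
    return out if out.ndim else float(out)


def gilliam_ratio(w, T, tau, traits: TraitParams, thermal: ThermalOxygenParams,
                  food: float = 1.0):
    """The dimensionless ratio P / (M w)."""
    P = energy_gain(w, T, tau, traits, thermal, food)
    out = P / (mortality(w, tau, traits) * np.asarray(w, dtype=float))
    return out if out.ndim else float(out)


def _preset_name(strategy: str, mos_regime: str) -> str:
    return f"{strategy}_{mos_regime}"


def run_sweep(strategies: Sequence[str] = ("slow", "fast"),
              mos_regimes: Sequence[str] = ("dome", "nodome"),
              T_grid: Iterable[float] | None = None,
              food_multipliers: Iterable[float] | None = None,
              sizes: Iterable[float] = DEFAULT_SIZES,
              include_life_history: bool = False) -> pd.DataFrame:
    """Factorial sweep of instantaneous performance metrics.

    One row per (strategy, mos_regime, T, food_multiplier, w) cell with the
    realized activity, feeding level, net energy gain, mortality, Gilliam
    ratio, production efficiency and the oxygen-limitation flag.  Cells
    where resting metabolism is oxygen-infeasible are flagged
    (``feasible = False``), never silently dropped.

    With ``include_life_history`` the sweep additionally calibrates the
    reaction-norm intercept per (strategy, mos_regime) at the reference
    temperature and baseline food, and attaches per-(T, food) asymptotic
    length ``L_inf`` and relative lifetime fitness ``R0_relative``
    (normalized to the maximum over temperatures within each
    (strategy, mos_regime, food) group).  This is substantially more
    expensive; prefer a coarse ``T_grid``.
    """
    rows = []
    for strategy in strategies:
        for mos_regime in mos_regimes:
            bundle = preset(_preset_name(strategy, mos_regime))
            traits, thermal = bundle.traits, bundle.thermal
            temps = list(T_grid) if T_grid is not None else list(bundle.sim.T_grid)
            foods = (list(food_multipliers) if food_multipliers is not None
                     else list(bundle.sim.food_multipliers))
            w_star = None
            if include_life_history:
                w_star = calibrate_wstar(bundle).w_star
            for food in foods:
                for T in temps:
                    cache = None
                    life = {}
                    if include_life_history:
                        cache = TauStarCache(bundle, T, food)
                        traj = grow_to_plateau(bundle, T, food, w_star, cache=cache)
                        fit = lifetime_fitness(bundle, T, food, w_star, cache=cache)
                        life = {
                            "L_inf": float(traj.L[-1]) if traj.feasible else np.nan,
                            "R0": fit.R0,
                        }
                    for w in sizes:
                        sol = optimal_activity(w, T, bundle, food)
                        f = feeding_level(w, T, sol.tau_star, traits, thermal, food)
                        eff = production_efficiency(w, T, sol.tau_star, traits,
                                                    thermal, food)
                        rows.append({
                            "strategy": strategy,
                            "mos_regime": mos_regime,
                            "T": float(T),
                            "food_multiplier": float(food),
                            "w": float(w),
                            "tau_star": sol.tau_star,
                            "tau_opt_unconstrained": sol.tau_opt_unconstrained,
                            "tau_max": sol.tau_max,
                            "f": float(f),
                            "P": sol.P,
                            "M": sol.M,
                            "P_over_Mw": sol.P / (sol.M * w),
                            "efficiency": float(eff),
                            "limited_by_oxygen": sol.limited_by_oxygen,
                            "feasible": sol.feasible,
                            **life,
                        })
    df = pd.DataFrame(rows)
    group_cols = ["strategy", "mos_regime", "food_multiplier"]
    if include_life_history:
        r0max = df.groupby(group_cols)["R0"].transform("max")
        df["R0_relative"] = np.where(r0max > 0, df["R0"] / r0max, 0.0)
    # Per-group normalization of P over temperatures (at each size), as the
    # scenario figures plot rates relative to their maximum.
    pmax = df.groupby(group_cols + ["w"])["P"].transform("max")
    df["P_relative"] = np.where(pmax > 0, df["P"] / pmax, np.nan)
    return df


def write_csv(df: pd.DataFrame, path, bundle: ParameterBundle | None = None) -> None:
    """Write a tidy CSV, prefixed by a comment row with the resolved params."""
    with open(path, "w") as handle:
        if bundle is not None:
            handle.write(f"# params {_params.resolved_json(bundle)}\n")
        df.to_csv(handle, index=False)
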