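"""Parameter bundles, presets and config file I/O.

The model is parametrized by four blocks:

* :class:`TraitParams` — one life-history strategy's metabolic, feeding and
  mortality coefficients (the slow/fast trait axis).
* :class:`ThermalOxygenParams` — Arrhenius scaling, the maximum-oxygen-supply
  (MOS) dome, ambient dissolved oxygen and the oxygen-cost coefficient.
* :class:`MRNParams` — the maturation reaction norm governing allocation of
  surplus energy to reproduction.
* :class:`SimulationSettings` — grids, integration horizon and tolerances.

Units throughout: grams (wet weight), years, degrees Celsius, mg O2 per litre
for ambient oxygen, and eV for the activation energy.  Several symbols of the
underlying model collide (the egestion fraction and the allocation function
are both conventionally written phi; the reaction-norm steepness and the
Arrhenius factor are both written c); here the egestion fraction is ``phi_e``,
the allocation function is ``psi`` and the reaction-norm steepness is
``c_mrn``, while ``c(T)`` stays with the Arrhenius factor.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any

import numpy as np
import yaml

__all__ = [
    "ParameterError",
    "TraitParams",
    "ThermalOxygenParams",
    "MRNParams",
    "SimulationSettings",
    "ParameterBundle",
    "PRESET_NAMES",
    "preset",
    "load_config",
    "serialize",
]


class ParameterError(ValueError):
    """Raised when a parameter bundle violates a model invariant."""


def _require(condition: bool, message: str) -> None:
    if not condition:
        raise ParameterError(message)


@dataclass(frozen=True)
class TraitParams:
    """Metabolic, feeding and mortality coefficients of one strategy.

    Parameters
    ----------
    beta : float
        Specific dynamic action (SDA): fraction of ingested food spent on
        absorption/assimilation.
    phi_e : float
        Fraction of ingested food lost to egestion and excretion.
    k : float
        Coefficient of standard metabolism, g^(1-n)·y⁻¹.
    k_a : float
        Coefficient of active metabolism, g·y⁻¹ (cost of activity at tau=1,
        scaling isometrically with weight).
    n : float
        Weight exponent of standard metabolism.
    gamma_theta : float
        Encountered food: clearance-rate coefficient times resource
        availability (gamma * Theta), g^(1-p)·y⁻¹.
    p : float
        Weight exponent of the clearance rate.
    h : float
        Coefficient of maximum consumption, g^(1-q)·y⁻¹.
    q : float
        Weight exponent of maximum consumption.
    rho : float
        Baseline mortality at w = 1 g and tau = 0, y⁻¹.
    mu : float
        Activity-related mortality coefficient, y⁻¹.
    """

    beta: float = 0.15
    phi_e: float = 0.25
    k: float = 1.0
    k_a: float = 4.0
    n: float = 0.88
    gamma_theta: float = 60.0
    p: float = 0.8
    h: float = 30.0
    q: float = 0.8
    rho: float = 0.1
    mu: float = 6.0

    def validate(self) -> "TraitParams":
        _require(self.beta >= 0, f"beta must be >= 0, got {self.beta}")
        _require(self.phi_e >= 0, f"phi_e must be >= 0, got {self.phi_e}")
        _require(
            self.beta + self.phi_e < 1,
            f"beta + phi_e must be < 1, got {self.beta + self.phi_e}",
        )
        for name in ("k", "k_a", "gamma_theta", "h", "rho", "mu"):
            value = getattr(self, name)
            _require(value > 0, f"{name} must be > 0, got {value}")
        for name in ("n", "p", "q"):
            value = getattr(self, name)
            _require(0 < value <= 1, f"{name} must be in (0, 1], got {value}")
        return self


@dataclass(frozen=True)
class ThermalOxygenParams:
    """Temperature and oxygen parameters.

    ``eta`` sets the width of the MOS dome and ``zeta`` its height; setting
    ``T_opt`` close to ``T_max`` together with a small ``eta`` emulates a MOS
    that rises continually up to the lethal temperature.  ``omega`` converts
    mass metabolized into oxygen used; its default is calibrated so that the
    preset scenarios retain aerobic scope at full activity (tau = 1) over
    mid-range temperatures, with oxygen limitation appearing only near the
    thermal extremes (see docs/methods.md).
    """

    E_a: float = 0.52  # activation energy, eV
    T0: float = 15.0  # reference temperature, degC (c(T0) = 1)
    T_max: float = 26.0  # lethal temperature, degC
    T_opt: float = 20.0  # temperature of maximum oxygen supply, degC
    eta: float = 3.0  # MOS dome-width exponent
    zeta: float = 0.5  # MOS level, g·y⁻¹ (per w^n)
    omega: float = 0.005  # oxygen cost per unit mass metabolized
    C_crit: float = 2.0  # ambient O2 at which supply ceases, mg·L⁻¹
    C_50: float = 4.0  # ambient O2 at 50% supply, mg·L⁻¹
    l: float = 10.0  # ambient O2 at 5 degC, mg·L⁻¹
    o2_decay: float = 0.01851  # exponential decline of dissolved O2, per degC
    normalize_mos: bool = True  # scale the dome so mos_level(T_opt) == zeta

    def validate(self) -> "ThermalOxygenParams":
        _require(self.T_opt < self.T_max, "T_opt must be < T_max")
        _require(self.C_crit < self.C_50, "C_crit must be < C_50")
        for name in ("eta", "zeta", "omega", "l"):
            value = getattr(self, name)
            _require(value > 0, f"{name} must be > 0, got {value}")
        return self


@dataclass(frozen=True)
class MRNParams:
    """Maturation reaction norm: logistic allocation to reproduction.

    ``w_star`` is the reaction-norm intercept (the weight of 50% allocation);
    it is normally calibrated by maximizing lifetime reproductive output at
    the reference temperature (see :func:`fishthermal.life_history.calibrate_wstar`)
    rather than set by hand — the default here is a pre-calibration
    placeholder.  ``slope`` shifts the intercept linearly with age
    (0 = flat reaction norm, the default).
    """

    w_star: float = 50.0  # allocation midpoint weight, g
    c_mrn: float = 0.5  # allocation steepness, g⁻¹
    slope: float = 0.0  # intercept shift with age, g·y⁻¹

    def validate(self) -> "MRNParams":
        _require(self.w_star > 0, f"w_star must be > 0, got {self.w_star}")
        _require(self.c_mrn > 0, f"c_mrn must be > 0, got {self.c_mrn}")
        return self


@dataclass(frozen=True)
class SimulationSettings:
    """Grids, integration horizon and numerical tolerances."""

    T_grid: tuple[float, ...] = tuple(float(x) for x in np.arange(5.0, 26.01, 0.25))
    food_multipliers: tuple[float, ...] = (2.0 / 3.0, 1.0, 4.0 / 3.0)
    w0: float = 0.1  # initial weight for growth integration, g
    t_horizon: float = 100.0  # integration horizon, y
    condition_factor: float = 0.01  # w = condition_factor * L^3, g·cm⁻³
    w_floor: float = 0.01  # weight below which shrinking stops, g
    tau_grid_points: int = 2001  # grid for the activity optimizer
    tau_tol: float = 1e-8  # golden-section tolerance on tau
    root_tol: float = 1e-10  # tolerance of the tau_max root solve
    ode_rtol: float = 1e-8  # relative tolerance of the growth ODE
    cache_points: int = 200  # weight-grid size of the tau* cache
    wstar_grid_points: int = 25  # log-grid size of the w* calibration
    wstar_rel_tol: float = 1e-3  # relative tolerance on calibrated w*
    random_seed: int = 0  # reserved; the model is deterministic

    def validate(self) -> "SimulationSettings":
        _require(self.w0 > 0, f"w0 must be > 0, got {self.w0}")
        _require(self.t_horizon > 0, f"t_horizon must be > 0, got {self.t_horizon}")
        _require(self.condition_factor > 0, "condition_factor must be > 0")
        _require(0 < self.w_floor <= self.w0, "need 0 < w_floor <= w0")
        _require(all(m > 0 for m in self.food_multipliers), "food multipliers must be > 0")
        return self


@dataclass(frozen=True)
class ParameterBundle:
    """A complete, validated model parametrization."""

    name: str
    traits: TraitParams
    thermal: ThermalOxygenParams
    mrn: MRNParams
    sim: SimulationSettings

    def validate(self) -> "ParameterBundle":
        self.traits.validate()
        self.thermal.validate()
        self.mrn.validate()
        self.sim.validate()
        return self

    def with_mrn(self, **kwargs: Any) -> "ParameterBundle":
        return replace(self, mrn=replace(self.mrn, **kwargs)).validate()

    def to_dict(self) -> dict[str, Any]:
        return {
            "preset": self.name,
            "traits": dataclasses.asdict(self.traits),
            "thermal_oxygen": dataclasses.asdict(self.thermal),
            "mrn": dataclasses.asdict(self.mrn),
            "simulation": {
                key: list(value) if isinstance(value, tuple) else value
                for key, value in dataclasses.asdict(self.sim).items()
            },
        }


# Table-1 trait columns for the two strategies.  The slow strategy minimizes
# mortality and metabolic costs at the expense of production (high activity
# cost k_a and activity mortality mu, strong refuge: low rho); the fast
# strategy maximizes production (doubled maximum consumption h, 50% higher
# standard metabolism k) at the cost of exposure (high rho).
_SLOW = TraitParams(k=1.0, k_a=4.0, n=0.88, h=30.0, rho=0.1, mu=6.0)
_FAST = TraitParams(k=1.5, k_a=2.0, n=0.75, h=60.0, rho=1.0, mu=1.0)

_PRESETS: dict[str, tuple[TraitParams, float, float, float]] = {
    # name: (traits, zeta, eta, T_opt)
    "slow_dome": (_SLOW, 0.5, 3.0, 20.0),
    "slow_nodome": (_SLOW, 0.5, 0.1, 25.0),
    "fast_dome": (_FAST, 1.0, 3.0, 20.0),
    "fast_nodome": (_FAST, 1.0, 0.1, 25.0),
}

PRESET_NAMES = tuple(_PRESETS)


def preset(name: str) -> ParameterBundle:
    """Return one of the four packaged scenarios.

    ``{slow,fast}`` selects the trait column; ``{dome,nodome}`` selects a
    dome-shaped MOS (eta=3, T_opt=20) or a MOS rising continually up to the
    lethal temperature (eta=0.1, T_opt=25).
    """
    try:
        traits, zeta, eta, t_opt = _PRESETS[name]
    except KeyError:
        raise ParameterError(
            f"unknown preset {name!r}; expected one of {', '.join(PRESET_NAMES)}"
        ) from None
    bundle = ParameterBundle(
        name=name,
        traits=traits,
        thermal=ThermalOxygenParams(zeta=zeta, eta=eta, T_opt=t_opt),
        mrn=MRNParams(),
        sim=SimulationSettings(),
    )
    return bundle.validate()


_SECTIONS = {
    "traits": TraitParams,
    "thermal_oxygen": ThermalOxygenParams,
    "mrn": MRNParams,
    "simulation": SimulationSettings,
}
_SECTION_ATTR = {
    "traits": "traits",
    "thermal_oxygen": "thermal",
    "mrn": "mrn",
    "simulation": "sim",
}


def _apply_section(obj: Any, cls: type, overrides: dict[str, Any], section: str) -> Any:
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(overrides) - valid
    if unknown:
        raise ParameterError(
            f"unknown field(s) {sorted(unknown)} in config section {section!r}"
        )
    coerced = {
        key: tuple(value) if isinstance(value, list) else value
        for key, value in overrides.items()
    }
    return replace(obj, **coerced)


def from_dict(data: dict[str, Any]) -> ParameterBundle:
    """Build a bundle from a plain mapping (the config-file schema).

    Top-level keys: ``preset`` plus any of ``traits``, ``thermal_oxygen``,
    ``mrn``, ``simulation``; unspecified fields fall back to the preset.
    """
    if not isinstance(data, dict):
        raise ParameterError("config must be a mapping")
    unknown = set(data) - ({"preset"} | set(_SECTIONS))
    if unknown:
        raise ParameterError(f"unknown top-level config key(s): {sorted(unknown)}")
    bundle = preset(data.get("preset", "slow_dome"))
    for section, cls in _SECTIONS.items():
        overrides = data.get(section) or {}
        if not isinstance(overrides, dict):
            raise ParameterError(f"config section {section!r} must be a mapping")
        if overrides:
            attr = _SECTION_ATTR[section]
            updated = _apply_section(getattr(bundle, attr), cls, overrides, section)
            bundle = replace(bundle, **{attr: updated})
    return bundle.validate()


def load_config(path: str | Path) -> ParameterBundle:
    """Load a YAML (or JSON) config file into a validated bundle."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data is None:
        data = {}
    return from_dict(data)


def serialize(bundle: ParameterBundle, path: str | Path | None = None) -> str:
    """Serialize a bundle to YAML; optionally write it to ``path``."""
    text = yaml.safe_dump(bundle.to_dict(), sort_keys=True)
    if path is not None:
        Path(path).write_text(text)
    return text


def resolved_json(bundle: ParameterBundle) -> str:
    """One-line JSON of the fully resolved bundle (for CSV header comments)."""
    return json.dumps(bundle.to_dict(), sort_keys=True, separators=(",", ":"))
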