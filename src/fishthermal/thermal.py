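"""Pure functions of temperature: Arrhenius scaling, dissolved oxygen and
the maximum-oxygen-supply (MOS) curve.

All temperatures are in degrees Celsius; conversion to Kelvin happens only
inside the Arrhenius evaluation.
"""

from __future__ import annotations

import numpy as np

from .params import ThermalOxygenParams

__all__ = [
    "BOLTZMANN_EV",
    "LethalTemperatureError",
    "arrhenius_factor",
    "ambient_oxygen",
    "mos_level",
    "oxygen_supply_coeff",
]

#: Boltzmann constant in eV·K⁻¹.
BOLTZMANN_EV = 8.617333262e-5

_CELSIUS_OFFSET = 273.15
_LN_HALF = np.log(0.5)


class LethalTemperatureError(ValueError):
    """Raised when a rate is requested above the lethal temperature T_max."""


def arrhenius_factor(T, params: ThermalOxygenParams):
    """Arrhenius temperature scaling c(T) = exp(E_a (T - T0) / (b T T0)).

    Temperatures enter in Kelvin; ``b`` is the Boltzmann constant in eV·K⁻¹.
    The factor equals 1 at the reference temperature ``params.T0`` and is
    strictly increasing in T.
    """
    T_K = np.asarray(T, dtype=float) + _CELSIUS_OFFSET
    T0_K = params.T0 + _CELSIUS_OFFSET
    out = np.exp(params.E_a * (T_K - T0_K) / (BOLTZMANN_EV * T_K * T0_K))
    return out if out.ndim else float(out)


def ambient_oxygen(T, params: ThermalOxygenParams):
    """Ambient dissolved oxygen (mg·L⁻¹), declining exponentially with T.

    ``l * exp(-o2_decay * (T - 5))``: an approximation to dissolved-oxygen
    saturation in seawater at 35 PSU, anchored at ``l`` mg·L⁻¹ at 5 °C.
    """
    T = np.asarray(T, dtype=float)
    out = params.l * np.exp(-params.o2_decay * (T - 5.0))
    return out if out.ndim else float(out)


def _check_lethal(T, params: ThermalOxygenParams) -> np.ndarray:
    T = np.asarray(T, dtype=float)
    if np.any(T > params.T_max):
        raise LethalTemperatureError(
            f"temperature above the lethal limit T_max={params.T_max} degC"
        )
    return T


def mos_level(T, params: ThermalOxygenParams, literal_n: float | None = None):
    """Maximum-oxygen-supply level lambda(T) (g·y⁻¹, per w^n).

    A flexible dome: with x = (T_max - T)/(T_max - T_opt),

        lambda(T) = zeta * x**eta * exp(eta * (1 - x))

    which is zero at the lethal temperature T_max and has its unique maximum
    zeta at T_opt.  With a small ``eta`` and ``T_opt`` near ``T_max`` the
    curve rises continually up to the lethal temperature instead of doming.

    With ``params.normalize_mos`` False the curve is ``zeta * x**eta *
    exp(-eta * x)`` (maximum zeta·e^-eta at T_opt).  ``literal_n`` replaces
    the exponential's coefficient eta by the given value, shifting the
    stationary point away from T_opt; it exists only for comparison against
    that variant and is not used by the model.
    """
    T = _check_lethal(T, params)
    x = (params.T_max - T) / (params.T_max - params.T_opt)
    coeff = params.eta if literal_n is None else literal_n
    out = params.zeta * np.power(x, params.eta) * np.exp(-coeff * x)
    if params.normalize_mos and literal_n is None:
        out = out * np.exp(params.eta)
    return out if out.ndim else float(out)


def oxygen_supply_coeff(T, params: ThermalOxygenParams):
    """Oxygen-supply coefficient S_O2(T) (g·y⁻¹, multiplies w^n).

    The MOS level lambda(T) scaled by a saturating function of ambient
    oxygen C(T): supply is 0 at C = C_crit, lambda/2 at C = C_50 and
    approaches lambda as C grows.  Ambient oxygen below C_crit yields 0
    (never negative).
    """
    lam = mos_level(T, params)
    C = ambient_oxygen(T, params)
    frac = 1.0 - np.exp((C - params.C_crit) * _LN_HALF / (params.C_50 - params.C_crit))
    out = lam * np.clip(frac, 0.0, 1.0)
    return out if np.ndim(out) else float(out)
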