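"""Independent, naively-coded evaluators of the model's closed forms.

These are deliberately written from the rate equations directly (plain
``math`` arithmetic, no reuse of the package's vectorized code paths) so
they can serve as oracles for the implementation.
"""

from __future__ import annotations

import math

import numpy as np

BOLTZMANN = 8.617333262e-5  # eV/K


def c_T(T, E_a, T0):
    TK = T + 273.15
    T0K = T0 + 273.15
    return math.exp(E_a * (TK - T0K) / (BOLTZMANN * TK * T0K))


def feeding(w, T, tau, tr, th, food=1.0):
    enc = tau * food * tr.gamma_theta * w ** tr.p
    if enc == 0:
        return 0.0
    return enc / (enc + tr.h * c_T(T, th.E_a, th.T0) * w ** tr.q)


def energy_gain(w, T, tau, tr, th, food=1.0):
    c = c_T(T, th.E_a, th.T0)
    f = feeding(w, T, tau, tr, th, food)
    return ((1 - tr.beta - tr.phi_e) * f * tr.h * c * w ** tr.q
            - c * tr.k * w ** tr.n - tau * c * tr.k_a * w)


def ambient_o2(T, th):
    return th.l * math.exp(-th.o2_decay * (T - 5.0))


def mos(T, th):
    x = (th.T_max - T) / (th.T_max - th.T_opt)
    lam = th.zeta * x ** th.eta * math.exp(-th.eta * x)
    if th.normalize_mos:
        lam *= math.exp(th.eta)
    return lam


def supply_coeff(T, th):
    C = ambient_o2(T, th)
    frac = 1.0 - math.exp((C - th.C_crit) * math.log(0.5) / (th.C_50 - th.C_crit))
    return mos(T, th) * max(0.0, frac)


def oxygen_demand(w, T, tau, tr, th, food=1.0):
    c = c_T(T, th.E_a, th.T0)
    f = feeding(w, T, tau, tr, th, food)
    return th.omega * c * (tr.beta * f * tr.h * w ** tr.q
                           + tr.k * w ** tr.n + tau * tr.k_a * w)


def aerobic_scope(w, T, tau, tr, th, food=1.0):
    return supply_coeff(T, th) * w ** tr.n - oxygen_demand(w, T, tau, tr, th, food)


def mortality(w, tau, tr):
    return (tr.rho + tr.mu * tau) * w ** (tr.q - 1.0)


def brute_force_tau_star(w, T, bundle, food=1.0, n=100_001):
    """Grid argmax of the constrained Gilliam objective (naive evaluators).

    Returns (tau_star, grid_step).  Mirrors the model's decision rule:
    maximize P/M where some feasible tau earns P > 0, else maximize P,
    restricted to the oxygen-feasible range.
    """
    tr, th = bundle.traits, bundle.thermal
    taus = np.linspace(0.0, 1.0, n)
    P = np.array([energy_gain(w, T, t, tr, th, food) for t in taus])
    M = np.array([mortality(w, t, tr) for t in taus])
    scope = np.array([aerobic_scope(w, T, t, tr, th, food) for t in taus])
    feasible = scope >= 0.0
    if not feasible[0]:
        return 0.0, taus[1] - taus[0]
    Pf = np.where(feasible, P, -np.inf)
    if np.max(Pf) > 0.0:
        obj = np.where(feasible, P / M, -np.inf)
    else:
        obj = Pf
    return float(taus[int(np.argmax(obj))]), float(taus[1] - taus[0])


def euler_r0(bundle, T, food, w_star, cache, dt=0.002, horizon=100.0):
    """Forward-Euler growth/survival/fitness integration (independent of
    the package's ODE solver); uses the package's tau*(w) cache but the
    naive rate evaluators above."""
    tr, th, sim = bundle.traits, bundle.thermal, bundle.sim
    w, H, R = sim.w0, 0.0, 0.0
    t = 0.0
    while t < horizon:
        tau = float(cache(w))
        P = energy_gain(w, T, tau, tr, th, food)
        psi = 1.0 / (1.0 + math.exp(-bundle.mrn.c_mrn * min(max(w - w_star, -700), 700)))
        R += psi * max(P, 0.0) * math.exp(-H) * dt
        H += mortality(w, tau, tr) * dt
        w = max(w + (1.0 - psi) * P * dt, sim.w_floor)
        t += dt
    return R
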