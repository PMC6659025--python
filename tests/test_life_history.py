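import dataclasses
import math

import numpy as np
import pytest

from fishthermal import (
    MRNParams,
    TauStarCache,
    allocation,
    asymptotic_weight_bound,
    calibrate_wstar,
    grow,
    grow_to_plateau,
    lifetime_fitness,
)

import oracles


def test_allocation_logistic_anchors():
    mrn = MRNParams(w_star=50.0, c_mrn=0.5)
    assert allocation(50.0, mrn) == 0.5
    assert allocation(60.0, mrn) == pytest.approx(1.0 / (1.0 + math.exp(-5.0)), rel=1e-12)
    assert allocation(1e9, mrn) == 1.0
    assert allocation(1e-9, mrn) == pytest.approx(1.0 / (1.0 + math.exp(25.0)), rel=1e-9)


def test_allocation_slope_shifts_midpoint_with_age():
    mrn = MRNParams(w_star=50.0, c_mrn=0.5, slope=10.0)
    assert allocation(50.0, mrn, t=0.0) == 0.5
    assert allocation(60.0, mrn, t=1.0) == 0.5  # midpoint moved to 60 g at age 1
    assert allocation(50.0, mrn, t=1.0) < 0.5


def test_growth_without_reproduction_reaches_energetic_asymptote(slow_dome):
    # with the allocation midpoint far beyond any attainable weight the
    # trajectory must plateau at the root of max_tau P(w) = 0
    bound = asymptotic_weight_bound(slow_dome, 15.0)
    traj = grow_to_plateau(slow_dome, 15.0, w_star=1e9, rel_tol=1e-5)
    assert traj.w[-1] == pytest.approx(bound, rel=0.01)
    assert np.all(np.diff(traj.w) >= -1e-9)


def test_survival_closed_form_under_constant_mortality(slow_dome):
    # q = 1 and vanishing activity mortality force M = rho, so S = exp(-rho t)
    traits = dataclasses.replace(slow_dome.traits, q=1.0, mu=1e-12, rho=0.3)
    bundle = dataclasses.replace(slow_dome, traits=traits)
    traj = grow(bundle, 15.0, w_star=1e9, horizon=20.0)
    assert np.allclose(traj.S, np.exp(-0.3 * traj.t), rtol=1e-6, atol=1e-9)


def test_survival_monotone_and_normalized(slow_dome, calibrated_slow, slow_cache_15):
    traj = grow(slow_dome, 15.0, w_star=calibrated_slow.w_star, cache=slow_cache_15)
    assert traj.S[0] == 1.0
    assert np.all(np.diff(traj.S) <= 0)
    assert np.all((traj.psi >= 0) & (traj.psi <= 1))


def test_unreachable_maturation_weight_kills_fitness(slow_dome, slow_cache_15):
    result = lifetime_fitness(slow_dome, 15.0, w_star=1e6, cache=slow_cache_15)
    assert result.R0 == pytest.approx(0.0, abs=1e-9)


def test_extreme_mortality_annihilates_fitness(slow_dome, calibrated_slow):
    traits = dataclasses.replace(slow_dome.traits, rho=100.0)
    bundle = dataclasses.replace(slow_dome, traits=traits)
    result = lifetime_fitness(bundle, 15.0, w_star=calibrated_slow.w_star)
    assert result.R0 < 1e-6 * calibrated_slow.R0


def test_fitness_converges_within_horizon(slow_dome, fast_dome,
                                          calibrated_slow, calibrated_fast,
                                          slow_cache_15, fast_cache_15):
    for bundle, cal, cache in ((slow_dome, calibrated_slow, slow_cache_15),
                               (fast_dome, calibrated_fast, fast_cache_15)):
        r100 = lifetime_fitness(bundle, 15.0, w_star=cal.w_star, cache=cache)
        traj50 = grow(bundle, 15.0, w_star=cal.w_star, horizon=50.0, cache=cache)
        assert r100.converged
        assert traj50.R0 == pytest.approx(r100.R0, rel=1e-3)


def test_fitness_matches_independent_euler_integration(slow_dome, calibrated_slow,
                                                       slow_cache_15):
    r = lifetime_fitness(slow_dome, 15.0, w_star=calibrated_slow.w_star,
                         cache=slow_cache_15)
    r_euler = oracles.euler_r0(slow_dome, 15.0, 1.0, calibrated_slow.w_star,
                               slow_cache_15, dt=0.002, horizon=60.0)
    # first-order Euler at this step size carries ~1% bias; the check guards
    # against structural errors (wrong integrand, survival form, clipping)
    assert r.R0 == pytest.approx(r_euler, rel=0.02)


def test_calibration_is_idempotent_and_beats_grid(slow_dome, calibrated_slow,
                                                  slow_cache_15):
    again = calibrate_wstar(slow_dome)
    assert again.w_star == calibrated_slow.w_star
    assert again.R0 == calibrated_slow.R0
    bound = asymptotic_weight_bound(slow_dome, 15.0)
    assert 0 < calibrated_slow.w_star < bound
    # external coarse-grid oracle: no grid point beats the calibrated optimum
    for w_star in np.geomspace(2.0, bound, 12):
        r = lifetime_fitness(slow_dome, 15.0, w_star=float(w_star),
                             cache=slow_cache_15)
        assert r.R0 <= calibrated_slow.R0 * (1 + 1e-9)


def test_maturation_happens_at_reaction_norm_size(slow_dome, calibrated_slow):
    # flat reaction norm: maturation at a fixed SIZE, so its AGE shifts with
    # growth speed while the weight at 50% allocation stays at w*
    ages = {}
    for T in (12.0, 15.0):
        traj = grow(slow_dome, T, w_star=calibrated_slow.w_star, n_out=2001)
        age = traj.maturation_age
        assert age is not None
        w_at_maturation = float(np.interp(age, traj.t, traj.w))
        assert w_at_maturation == pytest.approx(calibrated_slow.w_star, rel=0.02)
        ages[T] = age
    assert ages[15.0] != ages[12.0]
    # faster juvenile growth at the warmer temperature matures earlier
    assert ages[15.0] < ages[12.0]


def test_lethal_conditions_yield_degenerate_trajectory(slow_dome):
    traj = grow(slow_dome, 25.9, w_star=100.0)
    assert not traj.feasible
    assert traj.S[0] == 1.0
    assert np.all(traj.S[1:] == 0.0)
    result = lifetime_fitness(slow_dome, 25.9, w_star=100.0)
    assert result.R0 == 0.0
    assert not result.feasible
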