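import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fishthermal import (
    budget_state,
    energy_gain,
    feeding_level,
    mortality,
    oxygen_budget,
)

import oracles


def test_feeding_level_zero_without_activity(slow_dome):
    assert feeding_level(10.0, 15.0, 0.0, slow_dome.traits, slow_dome.thermal) == 0.0


def test_feeding_level_symmetric_half(slow_dome):
    # tau*gamma_theta = 30 = h and p = q, so encountered food equals the
    # half-saturation term exactly at the reference temperature
    f = feeding_level(10.0, 15.0, 0.5, slow_dome.traits, slow_dome.thermal)
    assert f == pytest.approx(0.5, rel=1e-12)


def test_feeding_level_warm_water_declines(slow_dome):
    # same symmetry at T=25 leaves f = 1/(1 + c(25))
    c25 = oracles.c_T(25.0, 0.52, 15.0)
    f = feeding_level(10.0, 25.0, 0.5, slow_dome.traits, slow_dome.thermal)
    assert f == pytest.approx(1.0 / (1.0 + c25), rel=1e-12)
    assert f == pytest.approx(0.331, abs=5e-4)


def test_energy_gain_resting_is_standard_metabolism(all_presets):
    for bundle in all_presets.values():
        P = energy_gain(10.0, 15.0, 0.0, bundle.traits, bundle.thermal)
        assert P == pytest.approx(-bundle.traits.k * 10.0 ** bundle.traits.n, rel=1e-12)


def test_energy_gain_worked_example(slow_dome):
    # 0.6 * 0.5 * 30 * 10^0.8 - 10^0.88 - 0.5*4*10
    expected = 0.6 * 0.5 * 30 * 10 ** 0.8 - 10 ** 0.88 - 20.0
    P = energy_gain(10.0, 15.0, 0.5, slow_dome.traits, slow_dome.thermal)
    assert P == pytest.approx(expected, rel=1e-12)
    assert P == pytest.approx(29.2, abs=0.05)


@pytest.mark.parametrize("name,w,tau,expected", [
    ("slow_dome", 10.0, 0.5, (0.1 + 3.0) * 10 ** -0.2),
    ("fast_dome", 10.0, 0.5, 1.5 * 10 ** -0.2),
    ("slow_dome", 1.0, 0.0, 0.1),  # rho is base mortality at w=1, tau=0
    ("fast_dome", 1.0, 0.0, 1.0),
])
def test_mortality_examples(all_presets, name, w, tau, expected):
    bundle = all_presets[name]
    assert mortality(w, tau, bundle.traits) == pytest.approx(expected, rel=1e-12)


def test_mortality_decreases_with_size(slow_dome):
    w = np.geomspace(0.1, 1000, 40)
    M = mortality(w, 0.3, slow_dome.traits)
    assert np.all(M > 0)
    assert np.all(np.diff(M) < 0)


def test_oxygen_demand_resting_reference(slow_dome):
    D, _, _ = oxygen_budget(10.0, 15.0, 0.0, slow_dome.traits, slow_dome.thermal)
    th = slow_dome.thermal
    assert D == pytest.approx(th.omega * 1.0 * 10 ** 0.88, rel=1e-12)


def test_strict_paper_demand_coincides_at_full_activity(all_presets):
    for bundle in all_presets.values():
        a = oxygen_budget(10.0, 18.0, 1.0, bundle.traits, bundle.thermal)
        b = oxygen_budget(10.0, 18.0, 1.0, bundle.traits, bundle.thermal,
                          strict_paper=True)
        assert a == pytest.approx(b, rel=1e-14)


def test_scope_strictly_decreasing_in_activity(all_presets):
    taus = np.linspace(0.0, 1.0, 101)
    for bundle in all_presets.values():
        _, _, scope = oxygen_budget(10.0, 15.0, taus, bundle.traits, bundle.thermal)
        assert np.all(np.diff(scope) < 0)


@settings(derandomize=True, max_examples=80, deadline=None)
@given(
    w=st.floats(min_value=0.05, max_value=5000.0),
    T=st.floats(min_value=5.0, max_value=25.9),
    tau=st.floats(min_value=0.0, max_value=0.99),
    dtau=st.floats(min_value=1e-4, max_value=0.01),
)
def test_feeding_level_bounded_and_increasing_in_activity(fast_dome, w, T, tau, dtau):
    tr, th = fast_dome.traits, fast_dome.thermal
    f0 = feeding_level(w, T, tau, tr, th)
    f1 = feeding_level(w, T, min(tau + dtau, 1.0), tr, th)
    assert 0.0 <= f0 <= 1.0
    assert f1 > f0


def test_feeding_level_saturates(slow_dome):
    # encountered food overwhelming max consumption drives f toward 1
    f = feeding_level(10.0, 15.0, 1.0, slow_dome.traits, slow_dome.thermal,
                      food=1e6)
    assert f > 0.999999


def test_all_rates_match_naive_oracle(all_presets):
    rng = np.random.default_rng(20240917)
    for bundle in all_presets.values():
        tr, th = bundle.traits, bundle.thermal
        for _ in range(25):
            w = float(10 ** rng.uniform(-1, 3))
            T = float(rng.uniform(5.0, 25.9))
            tau = float(rng.uniform(0.0, 1.0))
            food = float(rng.choice([2.0 / 3.0, 1.0, 4.0 / 3.0]))
            state = budget_state(w, T, tau, bundle, food)
            assert state.f == pytest.approx(oracles.feeding(w, T, tau, tr, th, food),
                                            rel=1e-12)
            assert state.P == pytest.approx(
                oracles.energy_gain(w, T, tau, tr, th, food), rel=1e-12)
            assert state.D_O2 == pytest.approx(
                oracles.oxygen_demand(w, T, tau, tr, th, food), rel=1e-12)
            assert state.S_O2w == pytest.approx(
                oracles.supply_coeff(T, th) * w ** tr.n, rel=1e-12)
            assert state.P_O2 == pytest.approx(
                oracles.aerobic_scope(w, T, tau, tr, th, food), rel=1e-12, abs=1e-15)
            assert state.M == pytest.approx(oracles.mortality(w, tau, tr), rel=1e-12)
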