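import pytest

from fishthermal import TauStarCache, calibrate_wstar, preset


@pytest.fixture(scope="session")
def slow_dome():
    return preset("slow_dome")


@pytest.fixture(scope="session")
def fast_dome():
    return preset("fast_dome")


@pytest.fixture(scope="session")
def slow_nodome():
    return preset("slow_nodome")


@pytest.fixture(scope="session")
def fast_nodome():
    return preset("fast_nodome")


@pytest.fixture(scope="session")
def all_presets(slow_dome, fast_dome, slow_nodome, fast_nodome):
    return {
        "slow_dome": slow_dome,
        "fast_dome": fast_dome,
        "slow_nodome": slow_nodome,
        "fast_nodome": fast_nodome,
    }


@pytest.fixture(scope="session")
def calibrated_slow(slow_dome):
    """Reaction-norm intercept calibrated at the reference temperature."""
    return calibrate_wstar(slow_dome)


@pytest.fixture(scope="session")
def calibrated_fast(fast_dome):
    return calibrate_wstar(fast_dome)


@pytest.fixture(scope="session")
def slow_cache_15(slow_dome):
    return TauStarCache(slow_dome, 15.0, 1.0)


@pytest.fixture(scope="session")
def fast_cache_15(fast_dome):
    return TauStarCache(fast_dome, 15.0, 1.0)
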