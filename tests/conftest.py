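import numpy as np
import pytest

from psmcea import UtilitySet, build_scenario


@pytest.fixture(scope="session")
def dmmr_scenario():
    """Bundled dMMR scenario (six strategies, synthetic trial curves)."""
    return build_scenario("dmmr")


@pytest.fixture(scope="session")
def pmmr_scenario():
    return build_scenario("pmmr")


@pytest.fixture()
def toy_scenario():
    """Two-strategy exponential scenario with closed-form life-year integrals."""
    return build_scenario("toy")


@pytest.fixture()
def utilities():
    return UtilitySet()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
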