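import numpy as np
import pytest

from balancemodel import load_scenario


@pytest.fixture(scope="session")
def fig1_additive():
    return load_scenario("fig1_additive")


@pytest.fixture(scope="session")
def fig1_multiplicative():
    return load_scenario("fig1_multiplicative")


@pytest.fixture(scope="session")
def fig2():
    return load_scenario("fig2")


@pytest.fixture(scope="session")
def fig3():
    return load_scenario("fig3")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20220901)
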