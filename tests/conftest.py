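import numpy as np
import pytest

from stochident.network import (ParameterSet, PropensityDescriptor,
                                ReactionNetwork)


@pytest.fixture(scope="session")
def pure_birth():
    """0 -> S at constant rate c; X(t) ~ Poisson(x0 + c t)."""
    net = ReactionNetwork(["S"], np.array([[1]]),
                          [PropensityDescriptor("zeroth", (), rate_param=0)],
                          ["c"])
    return net, ParameterSet(np.array([25.0]), ("c",)), np.array([0], np.int64)


@pytest.fixture(scope="session")
def pure_death():
    """S -> 0 at rate c X; E[X(t)] = x0 exp(-c t)."""
    net = ReactionNetwork(["S"], np.array([[-1]]),
                          [PropensityDescriptor("first", (0,), rate_param=0)],
                          ["c"])
    return net, ParameterSet(np.array([2.0]), ("c",)), np.array([20], np.int64)


@pytest.fixture(scope="session")
def infectious():
    from stochident.fixtures import fixture
    return fixture("infectious_disease")


@pytest.fixture(scope="session")
def mm():
    from stochident.fixtures import fixture
    return fixture("michaelis_menten")


@pytest.fixture(scope="session")
def toggle():
    from stochident.fixtures import fixture
    return fixture("toggle_switch")
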