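import numpy as np
import pytest

from caacircuit import (
    build_network,
    default_parameters,
    find_fixed_points,
)
from caacircuit.dosage import default_thresholds


@pytest.fixture(scope="session")
def strong_params():
    return default_parameters("strong")


@pytest.fixture(scope="session")
def weak_params():
    return default_parameters("weak")


@pytest.fixture(scope="session")
def strong_fixed_points(strong_params):
    return find_fixed_points(strong_params)


@pytest.fixture(scope="session")
def weak_fixed_points(weak_params):
    return find_fixed_points(weak_params)


@pytest.fixture(scope="session")
def strong_thresholds(strong_params):
    return default_thresholds(strong_params)


@pytest.fixture(scope="session")
def strong_network(strong_params):
    return build_network(strong_params)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260925)
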