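import numpy as np
import pytest
from hypothesis import settings

from striabot.network import build_hemisphere, build_network

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from striabot.params import ChannelGrid, ConnectivityKernel


@pytest.fixture(scope="session")
def grid():
    return ChannelGrid()


@pytest.fixture(scope="session")
def kernel():
    return ConnectivityKernel.default()


@pytest.fixture(scope="session")
def hemisphere_spec(grid, kernel):
    return build_hemisphere(grid, kernel, seed=0)


@pytest.fixture(scope="session")
def full_spec(grid, kernel):
    return build_network(grid, kernel, seed=0)


@pytest.fixture(scope="session")
def toy_grid():
    # two channels side by side (wrapped 1x2): 160 neurons total
    return ChannelGrid(rows=1, cols=2)


@pytest.fixture(scope="session")
def toy_spec(toy_grid, kernel):
    return build_hemisphere(toy_grid, kernel, seed=7)


@pytest.fixture(scope="session")
def run_cache():
    """Session cache of full paradigm runs shared across acceptance tests."""
    return {}
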