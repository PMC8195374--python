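import numpy as np
import pytest

from gammaecho import NetworkConfig, build_connectivity


@pytest.fixture(scope="session")
def default_config() -> NetworkConfig:
    return NetworkConfig()


@pytest.fixture(scope="session")
def small_config() -> NetworkConfig:
    """A 50-cell network for cheap structural tests."""
    return NetworkConfig(n_e=40, n_i=10)


@pytest.fixture(scope="session")
def small_connectivity(small_config):
    return build_connectivity(small_config, seed=7)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
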