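import numpy as np
import pytest

from senotf import SimulationConfig, generate_expression


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(n_genes=300, n_promoters=300, seed=7)


@pytest.fixture(scope="session")
def small_matrix(small_config):
    matrix, truth = generate_expression(small_config)
    return matrix, truth


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20140721)
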