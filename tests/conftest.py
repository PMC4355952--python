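import numpy as np
import pytest

from chd8net.simulate import SimulationConfig, gen_genome


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(seed=42, n_genes=60, risk_size=12)


@pytest.fixture(scope="session")
def small_genome(small_config):
    return gen_genome(small_config)
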