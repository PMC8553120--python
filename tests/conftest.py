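import numpy as np
import pytest

from aprt.design import FactorConfig, generate_design, generate_practice


@pytest.fixture(scope="session")
def config():
    return FactorConfig()


@pytest.fixture(scope="session")
def design(config):
    return generate_design(config, seed=11)


@pytest.fixture(scope="session")
def practice(config):
    return generate_practice(config, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
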