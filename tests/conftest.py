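import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import pinedrought as pdr

settings.register_profile(
    "ci", derandomize=True, max_examples=50, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def design():
    return pdr.ExperimentDesign()


@pytest.fixture(scope="session")
def params():
    return pdr.default_params()


@pytest.fixture(scope="session")
def env(design):
    return pdr.gen_environment(design)


@pytest.fixture(scope="session")
def needles(design, params):
    return pdr.gen_needle_obs(design, params)


@pytest.fixture(scope="session")
def dendro_data(design, params, env):
    return pdr.gen_dendro(design, params, env)


@pytest.fixture(scope="session")
def sapflow_data(design, params, env):
    return pdr.gen_sapflow(design, params, env)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
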