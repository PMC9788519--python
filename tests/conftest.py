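import numpy as np
import pytest

from phenorevert.pipeline import _log_matrix
from phenorevert.synthgen import GeneratorConfig, generate_population


@pytest.fixture(scope="session")
def default_config() -> GeneratorConfig:
    return GeneratorConfig(seed=0)


@pytest.fixture(scope="session")
def population(default_config):
    """Default cross-sectional cohort (400 HC + 400 acute, 38-var panel)."""
    return generate_population(default_config)


@pytest.fixture(scope="session")
def population_logx(population):
    return _log_matrix(population)


@pytest.fixture(scope="session")
def population_y(population):
    return (population.data["cohort"] != "HC").astype(int).to_numpy()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
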