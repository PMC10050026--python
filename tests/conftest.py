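import numpy as np
import pytest

from limbproj import PopulationSpec, generate_population
from limbproj.experiment import run_experiment

DEFAULT_SEED = 1


@pytest.fixture(scope="session")
def default_spec():
    return PopulationSpec(seed=DEFAULT_SEED)


@pytest.fixture(scope="session")
def default_population(default_spec):
    return generate_population(default_spec)


@pytest.fixture(scope="session")
def default_table(default_spec, default_population):
    """Full 60-limb x 28-pose measurement table under default settings."""
    return run_experiment(default_population, spec=default_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
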