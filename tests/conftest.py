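import numpy as np
import pytest

from climsuit import ExperimentConfig, ScenarioConfig, gen_scenario


@pytest.fixture(scope="session")
def small_scenario():
    """A reduced landscape (32x32 per region) for fast unit tests."""
    return gen_scenario(ScenarioConfig(rows=32, cols=32, seed=7))


@pytest.fixture(scope="session")
def small_config():
    return ExperimentConfig(scenario=ScenarioConfig(rows=32, cols=32, seed=7),
                            n_sets=3, n_points=50, n_test_points=50)


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
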