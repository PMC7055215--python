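import numpy as np
import pytest

from kirbyhorizon.instrument import MCQ27
from kirbyhorizon.simulate import PopulationConfig, simulate_study


@pytest.fixture(scope="session")
def instrument():
    return MCQ27


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_study():
    """A small simulated study reused across read-only tests."""
    cfg = PopulationConfig(n_subjects=12, games_per_cell=8, seed=77)
    truth, responses, trials = simulate_study(cfg)
    return cfg, truth, responses, trials
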