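import numpy as np
import pytest

from thermoact.simulate import SimulationConfig, make_cohort
from thermoact.state_space import SSParams


@pytest.fixture(scope="session")
def small_cohort():
    """A 2M + 2F, 6-day cohort with the default noise model."""
    cfg = SimulationConfig(n_male=2, n_female=2, days=6, seed=11)
    return make_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def nominal_params():
    """Parameters at the pooled population values."""
    return SSParams(a1=0.0016, a2=-0.0199, t_min=35.0)
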