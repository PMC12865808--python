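import numpy as np
import pytest

from dyadsync import SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """A short, fast cohort configuration (one 300 s phase per dyad)."""
    return SimulationConfig(
        n_dyads_per_condition=1,
        phase_plan=(("manipulation", 300.0, 30.0),),
        seed=7,
    )
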