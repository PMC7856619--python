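import logging

import numpy as np
import pytest

from mrkit.simulate import SimulationConfig, simulate_two_sample

# keep per-variant INFO chatter out of test output
logging.getLogger("mrkit").setLevel(logging.WARNING)


@pytest.fixture
def rng():
    return np.random.default_rng(11)


@pytest.fixture
def smoking_like_study():
    """One clean (no-pleiotropy) simulated study at smoking-preset sample sizes."""
    return simulate_two_sample(SimulationConfig(J=150, beta_true=0.3, seed=7))
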