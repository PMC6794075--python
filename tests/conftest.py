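import numpy as np
import pytest

from reachprior.synthetic import SimConfig, simulate_session


@pytest.fixture(scope="session")
def small_session():
    """A compact synthetic session shared by the integration-style tests."""
    return simulate_session(SimConfig(n_units_per_area=16, n_blocks=28, seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
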