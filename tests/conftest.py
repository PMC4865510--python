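import numpy as np
import pytest

from drivefatigue import simulate


@pytest.fixture(scope="session")
def session_pair():
    """One short well-rested / sleep-deprived session pair (shared seed)."""
    well = simulate.generate_session(simulate.preset("well_rested", seed=11, duration_s=120))
    sleep = simulate.generate_session(simulate.preset("sleep_deprived", seed=11, duration_s=120))
    return well, sleep


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
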