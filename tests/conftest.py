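import numpy as np
import pytest

from eegrt.simulate import SimConfig, simulate_session

# A short session (10 min, cues every ~40 s) keeps unit tests fast while
# exercising the same code paths as the 2-hour default.
SMALL_SESSION = dict(
    session_length_s=600.0,
    cue_interval_mean_s=40.0,
    cue_interval_sd_s=10.0,
    min_gap_s=10.0,
)


@pytest.fixture(scope="session")
def small_session():
    """Null (zero-coupling) short session."""
    return simulate_session(SimConfig(seed=11, **SMALL_SESSION))


@pytest.fixture(scope="session")
def coupled_session():
    """Short session with a planted O1-alpha coupling."""
    return simulate_session(
        SimConfig(seed=5, coupling={("O1", "Alpha"): 0.3}, **SMALL_SESSION)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
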