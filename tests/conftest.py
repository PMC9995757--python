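import numpy as np
import pytest

from nearfall import simulate, tilt


@pytest.fixture(scope="session")
def small_session():
    """A 120 s simulated session with default mix and noise (seed 7)."""
    session, events, script = simulate.simulate_session(120.0, seed=7)
    return session, events, script


@pytest.fixture(scope="session")
def small_tilt(small_session):
    session, _, _ = small_session
    return tilt.estimate_session_tilt(session)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
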