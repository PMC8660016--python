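import numpy as np
import pytest

from whisklab import SessionParams, decompose, generate_session


@pytest.fixture(scope="session")
def long_session():
    """600 s default-parameter session, shared across recovery tests."""
    return generate_session(SessionParams(duration=600.0, seed=1))


@pytest.fixture(scope="session")
def long_decomposition(long_session):
    return decompose(long_session.angle)


@pytest.fixture(scope="session")
def short_session():
    """120 s session for cheaper structural tests."""
    return generate_session(SessionParams(duration=120.0, seed=5))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
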