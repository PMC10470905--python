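import numpy as np
import pytest

from streak.synthetic import fixture_small


@pytest.fixture(scope="session")
def small_joint():
    """Tiny deterministic paired dataset shared across fast tests."""
    return fixture_small()


@pytest.fixture()
def rng():
    return np.random.default_rng(20231)
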