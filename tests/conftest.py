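import numpy as np
import pytest

from dissipath import ReactionScheme, load_fixture
from dissipath.synthetic_data import SchemeSamplerConfig, sample_schemes


@pytest.fixture(scope="session")
def records():
    return load_fixture()


@pytest.fixture
def two_state():
    return ReactionScheme(2, (2.0, 1.0, 1.0, 1.0), 1e-3, 1e-4)


@pytest.fixture
def three_state():
    return ReactionScheme(3, (2.0, 1.0, 1.0, 1.0, 1.0, 1.0), 1e-3, 1e-4)


@pytest.fixture
def four_state():
    return ReactionScheme(4, (10.0, 1.0, 4.0, 2.0, 6.0, 3.0, 8.0, 1.0), 1e-3, 1e-4)


@pytest.fixture(scope="session")
def random_schemes():
    """A modest bank of sampled schemes per cycle size for property tests."""
    return {
        n: sample_schemes(SchemeSamplerConfig(n_states=n, seed=100 + n), 50)
        for n in (2, 3, 4)
    }
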