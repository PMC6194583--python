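import numpy as np
import pytest

from desmoke import make_fixture_set


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def perlin_fixtures():
    """Small shared perlin fixture set for property tests."""
    return make_fixture_set(4, size=(48, 48), seed=7, profile="perlin")


@pytest.fixture(scope="session")
def smooth_fixtures():
    """Small shared smooth-veil fixture set with known ground truth."""
    return make_fixture_set(4, size=(48, 48), seed=7, profile="smooth_veil")
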