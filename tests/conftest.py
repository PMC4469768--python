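import numpy as np
import pytest

from rgfscm import FusionConfig, PhantomSpec, make_phantom_pair


@pytest.fixture
def rng():
    return np.random.default_rng(20150603)


@pytest.fixture(scope="session")
def phantom_pair():
    """Default 128x128 complementary phantom pair."""
    return make_phantom_pair(PhantomSpec(seed=7))


@pytest.fixture(scope="session")
def small_phantom_pair():
    """A 32x32 pair, cheap enough for loop oracles."""
    return make_phantom_pair(PhantomSpec(height=32, width=32, structure_scale=6.0, seed=3))


@pytest.fixture
def default_config():
    return FusionConfig()
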