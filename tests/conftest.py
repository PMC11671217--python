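import numpy as np
import pytest

from pleuraseg.phantom import PhantomConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_config():
    """Fast 32x32 phantom configuration for unit tests."""
    return PhantomConfig(image_size=32, seed=7)


@pytest.fixture
def default_config():
    return PhantomConfig(seed=7)


def random_mask(rng, shape=(16, 16), p=0.3):
    return rng.random(shape) < p
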