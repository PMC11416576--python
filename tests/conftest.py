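import numpy as np
import pytest

from fundusseg import phantom


@pytest.fixture(scope="session")
def small_phantom_cfg():
    return phantom.PhantomConfig(image_size=(64, 64))


@pytest.fixture(scope="session")
def small_sample(small_phantom_cfg):
    return phantom.generate_phantom(small_phantom_cfg, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
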