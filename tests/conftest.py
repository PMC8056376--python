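import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_region_image():
    """Bright square on a dark ground, no noise: a trivially segmentable scene."""
    image = np.full((48, 48), 0.15)
    image[12:36, 14:34] = 0.75
    return image
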