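import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def disk_mask(shape, center, radius):
    """Boolean disk: pixel centers within ``radius`` of ``center``."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return np.hypot(yy - center[0], xx - center[1]) <= radius


@pytest.fixture
def make_disk_mask():
    return disk_mask
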