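import numpy as np
import pytest
from hypothesis import settings

from octenhance import acquire_frames, make_phantom

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def phantom():
    """Default 128x256 phantom scene used across tests."""
    return make_phantom(128, 256, seed=7)


@pytest.fixture(scope="session")
def noisefree_phantom():
    """Phantom with speckle and sensor noise disabled."""
    return make_phantom(128, 256, seed=7, speckle_shape=np.inf, sensor_sigma=0.0)


@pytest.fixture()
def aligned_stack(phantom):
    """Motion-free 8-frame acquisition at default noise."""
    return acquire_frames(phantom, 8, (0.0, 0.0), 0.0, seed=21)
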