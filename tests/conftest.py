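import numpy as np
import pytest

from coroseg.phantoms import make_tube
from coroseg.volume import Volume


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_volume(rng):
    return Volume(
        data=rng.random((12, 14, 16)),
        spacing=(1.2, 0.8, 0.8),
        origin=(-4.0, 2.5, 3.5),
    )


@pytest.fixture(scope="session")
def noisy_cylinder():
    """Bright tube of radius 3 along z in a 32-cube, with Gaussian noise."""
    vol, mask = make_tube(32, axis=0, radius=3.0, contrast=1.0)
    rng = np.random.default_rng(7)
    noisy = Volume(data=vol.data + rng.normal(0.0, 0.1, vol.shape))
    return noisy, vol, mask
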