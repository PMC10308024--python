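import numpy as np
import pytest

from hippofactory import phantom as ph
from hippofactory.io_prep import z_normalize


@pytest.fixture(scope="session")
def default_phantom():
    """One default phantom (volume, labels), shared across tests."""
    return ph.make_hippocampus_phantom(ph.PhantomSpec())


@pytest.fixture(scope="session")
def noiseless_phantom():
    spec = ph.PhantomSpec(noise_sd=0.0, bias_amplitude=0.0)
    return ph.make_hippocampus_phantom(spec)


@pytest.fixture(scope="session")
def small_scene():
    """A compact head scene at canonical poses (kept small for speed)."""
    return ph.make_head_scene(ph.PhantomSpec(grid_shape=(16, 16, 16)),
                              scene_shape=(48, 48, 48))


def normalized_image(vol):
    return z_normalize(vol).data


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
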