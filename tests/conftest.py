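import numpy as np
import pytest

import cedsim as cs


@pytest.fixture(scope="session")
def slab_phantom():
    """Uniform WM slab, fibres along x, FA 0.7, VF_ECS 0.30."""
    return cs.generate_phantom(cs.PhantomSpec(shape=(16, 16, 16), seed=1))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260928)


def make_scalar(data, vox=2.0, mask=None):
    aff = np.diag([vox, vox, vox, 1.0])
    return cs.ScalarVolume(np.asarray(data, dtype=float), aff, mask)


def isotropic_tensor(shape, value, vox=2.0, mask=None):
    data = np.zeros(shape + (6,))
    data[..., 0] = data[..., 2] = data[..., 5] = value
    aff = np.diag([vox, vox, vox, 1.0])
    return cs.TensorVolume(data, aff, mask)
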