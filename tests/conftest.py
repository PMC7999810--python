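import numpy as np
import pytest

from infarctseg import BinaryMask, PhantomSpec, VolumeImage, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_phantom():
    """A 48^3 single-lesion phantom (volume, truth mask) used across tests."""
    spec = PhantomSpec(shape=(48, 48, 48), n_lesions=1, lesion_axes_range=(4.0, 6.0), seed=11)
    return generate_phantom(spec)


@pytest.fixture
def random_mask_pair(rng):
    """Two random, overlapping small masks with guaranteed nonempty foreground."""

    def make(shape=(10, 10, 10), p=0.2):
        while True:
            x = (rng.random(shape) < p).astype(np.uint8)
            y = (rng.random(shape) < p).astype(np.uint8)
            if x.any() and y.any():
                return BinaryMask(data=x), BinaryMask(data=y)

    return make


@pytest.fixture
def volume_cube(rng):
    data = rng.random((6, 7, 8)).astype(np.float32)
    return VolumeImage(data=data, spacing=(1.0, 1.0, 1.0), subject_id="c0001s0001t01")
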