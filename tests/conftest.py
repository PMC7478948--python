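import numpy as np
import pytest

from ctwml import ImageVolume, PhantomSpec, generate_pair


@pytest.fixture(scope="session")
def moderate_pair():
    """One deterministic phantom pair with moderate lesion load."""
    return generate_pair(PhantomSpec(seed=7, fazekas_target="2"))


@pytest.fixture(scope="session")
def severe_pair():
    return generate_pair(PhantomSpec(seed=8, fazekas_target="3"))


@pytest.fixture()
def unit_mask():
    """10x10x10 binary mask at 1 mm isotropic spacing, 1000 foreground voxels."""
    return ImageVolume.from_spacing(np.ones((10, 10, 10), dtype=np.uint8),
                                    (1.0, 1.0, 1.0), "mask")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
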