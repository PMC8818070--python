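import numpy as np
import pytest

from fetmirror import (
    LesionSpec,
    PhantomSpec,
    SeedSet,
    SUVImage,
    VoxelMask,
    generate_phantom,
    standard_phantom,
)

SMALL_SHAPE = (40, 48, 40)
SMALL_SPACING = (2.0, 2.0, 2.0)


def small_phantom_spec(**overrides):
    """A compact phantom used by most unit tests: one 8 mm lesion at +20 mm."""
    defaults = dict(
        shape=SMALL_SHAPE,
        spacing=SMALL_SPACING,
        brain_semiaxes_mm=(36.0, 44.0, 36.0),
        lesions=[LesionSpec(centre_mm=(20.0, 0.0, 0.0), radius_mm=8.0, suv=3.0)],
        rng_seed=0,
    )
    defaults.update(overrides)
    return PhantomSpec(**defaults)


@pytest.fixture(scope="session")
def small_phantom():
    return generate_phantom(small_phantom_spec())


@pytest.fixture(scope="session")
def std_phantom():
    """The full-size default study phantom (noiseless)."""
    return standard_phantom()


@pytest.fixture
def lesion_seed(small_phantom):
    centre = np.argwhere(small_phantom.true_lesions[0].voxels).mean(axis=0)
    return SeedSet([tuple(int(round(c)) for c in centre)])


@pytest.fixture
def uniform_image():
    """4x4x4 image of ones at 2 mm spacing with a full brain mask."""
    img = SUVImage(voxels=np.ones((4, 4, 4)), spacing=(2, 2, 2))
    brain = VoxelMask(voxels=np.ones((4, 4, 4), dtype=bool), spacing=(2, 2, 2))
    return img, brain
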