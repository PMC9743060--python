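import numpy as np
import pytest

import phmribold as pb

# reduced test geometry: half the in-plane matrix at doubled voxel size,
# all 18 slices kept so through-plane parameters stay well conditioned
RED_SHAPE = (48, 48, 18)
RED_VS = (0.375, 0.375, 0.75)
# smallest useful geometry for plumbing tests
TINY_SHAPE = (24, 24, 6)
TINY_VS = (0.75, 0.75, 1.5)


@pytest.fixture(scope="session")
def atlas12():
    return pb.make_atlas(12, RED_SHAPE, voxel_size=RED_VS, seed=1)


@pytest.fixture(scope="session")
def anatomy12(atlas12):
    return pb.AnalyticAnatomy.from_atlas(atlas12, seed=1)


@pytest.fixture(scope="session")
def template12(atlas12, anatomy12):
    return anatomy12.on_grid(atlas12.labels.shape, atlas12.voxel_size)


@pytest.fixture(scope="session")
def atlas_tiny():
    return pb.make_atlas(4, TINY_SHAPE, voxel_size=TINY_VS, seed=2)


def center_mm(shape, voxel_size):
    return (np.asarray(shape) - 1) / 2.0 * np.asarray(voxel_size)
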