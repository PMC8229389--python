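import numpy as np
import pytest

from gsirads.grids import REFERENCE, TumorMask, VolumeGrid
from gsirads.synthetic import make_atlas


def make_grid(data, spacing=(1.0, 1.0, 1.0), space=REFERENCE, origin=None):
    """Axis-aligned grid with the world origin at the volume center by
    default, so the midplane x = 0 is honored for even x-dimensions."""
    data = np.asarray(data)
    affine = np.eye(4)
    for ax in range(3):
        affine[ax, ax] = spacing[ax]
        if origin is None:
            affine[ax, 3] = -(data.shape[ax] - 1) / 2.0 * spacing[ax]
        else:
            affine[ax, 3] = origin[ax]
    return VolumeGrid(data=data, affine=affine, space=space)


def make_mask(data, spacing=(1.0, 1.0, 1.0), space=REFERENCE, origin=None):
    return TumorMask(grid=make_grid(np.asarray(data, dtype=np.uint8), spacing, space, origin))


def random_blob_mask(rng, shape=(16, 16, 16), density=0.08, spacing=(1.0, 1.0, 1.0)):
    """Sparse random foreground: a hard case for component analysis."""
    data = (rng.random(shape) < density).astype(np.uint8)
    return make_mask(data, spacing=spacing)


@pytest.fixture(scope="session")
def atlas_small():
    """Coarse synthetic atlas: 32 voxels at 4 mm, 6 parcels, 2 tract
    pairs.  Shared across tests; treat as read-only."""
    return make_atlas(shape=(32, 32, 32), spacing=(4.0, 4.0, 4.0), n_parcels=6, n_tract_pairs=2, seed=11)


@pytest.fixture(scope="session")
def atlas_default():
    """Default-resolution atlas: 64 voxels at 2 mm."""
    return make_atlas(seed=7)
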