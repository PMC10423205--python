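import numpy as np
import pytest

from hepatoscore import LiverMask, PhantomSpec, VfaProtocol, VoxelGeometry


@pytest.fixture
def protocol() -> VfaProtocol:
    return VfaProtocol()


@pytest.fixture
def small_phantom_spec() -> PhantomSpec:
    geom = VoxelGeometry((24, 24, 16), (2.0, 2.0, 2.0))
    return PhantomSpec(geom, liver_semi_axes_mm=(20.0, 16.0, 12.0),
                       rr_mean=0.5, rr_spatial_sd=0.08, seed=11)


@pytest.fixture
def flat_mask():
    """Mask of 1000 voxels at the interpolated protocol spacing (5.07 ml)."""
    geom = VoxelGeometry((10, 10, 10), (1.3, 1.3, 3.0))
    return LiverMask(np.ones((10, 10, 10), dtype=bool), geom)
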