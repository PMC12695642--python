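import numpy as np
import pytest

from pxct import forward, phantom


@pytest.fixture(scope="session")
def small_phantom():
    return phantom.make_phantom(48, voxel_size_nm=30.0, texture=0.4, rng_seed=3)


@pytest.fixture(scope="session")
def static_series(small_phantom):
    plan = phantom.AcquisitionPlan(angles=phantom.equispaced_angles(120))
    return forward.acquire_series(small_phantom, None, plan)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def pillar_interior_mask(shape, radius_frac=0.40, margin=6):
    """Voxels that are both inside the phantom pillar and away from edges."""
    nz, ny, nx = shape
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    yy, xx = np.mgrid[:ny, :nx]
    pillar = np.hypot(yy - cy, xx - cx) <= radius_frac * min(ny, nx)
    mask = np.zeros(shape, dtype=bool)
    mask[margin:-margin, margin:-margin, margin:-margin] = True
    return mask & pillar[None]
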