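import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import traveltime as tt

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


SINGAPORE_EXTENT = tt.Extent(103.6091, 104.0858, 1.1664, 1.4714)


@pytest.fixture
def singapore_extent():
    """The GADM level-0 bounding box of Singapore in decimal degrees."""
    return SINGAPORE_EXTENT


@pytest.fixture
def singapore_grid(singapore_extent):
    """Singapore extent snapped to the global 30-arc-second lattice."""
    return tt.snap_extent(singapore_extent, tt.RES_30_ARCSEC)


def random_surface(rng, nrow, ncol, mask_prob=0.0, planar=False):
    """Random strictly-positive friction with an optional random mask."""
    values = np.exp(rng.uniform(np.log(0.01), np.log(0.1), size=(nrow, ncol)))
    mask = rng.random((nrow, ncol)) < mask_prob
    if planar:
        grid = tt.GridSpec(
            extent=tt.Extent(0.0, ncol * 100.0, 0.0, nrow * 100.0),
            resolution_x=100.0,
            resolution_y=100.0,
            nrow=nrow,
            ncol=ncol,
            crs_kind="planar",
        )
        return tt.FrictionSurface(grid, values, mask)
    surf = tt.synth_friction(nrow, ncol, "uniform", 0.01)
    return tt.FrictionSurface(surf.grid, values, mask)
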