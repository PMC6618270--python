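import numpy as np
import pytest

import stenoflow as sf


@pytest.fixture(scope="session")
def geometry():
    return sf.build_geometry()


@pytest.fixture(scope="session")
def grid(geometry):
    return sf.default_grid(geometry)


@pytest.fixture(scope="session")
def segmentation(geometry, grid):
    return sf.segment_lumen(geometry, grid)


@pytest.fixture(scope="session")
def flow_re2000(geometry, grid):
    """Turbulence-mapped condition at 20 mL/s (Re ~ 2000)."""
    cond = sf.flow_condition(20e-6, geometry)
    return sf.turbulence_field(geometry, cond, grid)


@pytest.fixture(scope="session")
def flow_re1000(geometry, grid):
    """Turbulence-mapped condition at 10 mL/s (Re ~ 1000)."""
    cond = sf.flow_condition(10e-6, geometry)
    return sf.turbulence_field(geometry, cond, grid)


@pytest.fixture(scope="session")
def flow_increased(geometry, grid):
    """Velocity-mapped increased-flow case at 56 mL/s."""
    cond = sf.flow_condition(56e-6, geometry)
    return sf.mean_velocity_field(geometry, cond, grid)


def make_uniform_flow(u_vector, ivsd_vector=(0.0, 0.0, 0.0), shape=(12, 10, 10)):
    """A straight-pipe flow field with spatially uniform velocity and IVSD."""
    geometry = sf.build_geometry(area_reduction=0.0)
    grid = sf.GridSpec(
        shape=shape,
        voxel_size=1.5e-3,
        origin=(-shape[0] * 0.75e-3, -shape[1] * 0.75e-3, -shape[2] * 0.75e-3),
    )
    seg = sf.segment_lumen(geometry, grid)
    mean_velocity = np.zeros((3, *shape))
    ivsd = np.zeros((3, *shape))
    for a in range(3):
        mean_velocity[a][seg.mask] = u_vector[a]
        ivsd[a][seg.mask] = ivsd_vector[a]
    return sf.FlowField(
        grid=grid,
        geometry=geometry,
        fluid=sf.WATER_23C,
        condition=None,
        mean_velocity=mean_velocity,
        ivsd=ivsd,
        lumen_mask=seg.mask.copy(),
    )


@pytest.fixture()
def uniform_flow_factory():
    return make_uniform_flow
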