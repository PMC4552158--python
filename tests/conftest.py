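import numpy as np
import pytest

import rootct as rc


@pytest.fixture(scope="session")
def small_phantom():
    """A 96-cube three-root phantom shared by protocol-level tests."""
    spec = rc.PhantomSpec(shape=(96, 96, 96), seed=3)
    volume, truth = rc.generate_phantom(spec)
    return spec, volume, truth


@pytest.fixture(scope="session")
def small_phantom_examples(small_phantom):
    _, volume, truth = small_phantom
    return rc.example_coordinates(volume, truth, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def straight_tube_mask(shape, axis_point_yx, radius_voxels, z_range=None):
    """Axis-aligned (z) solid cylinder mask, rasterised by centre-inside."""
    nz, ny, nx = shape
    z0, z1 = (0, nz) if z_range is None else z_range
    y, x = np.mgrid[:ny, :nx]
    cy, cx = axis_point_yx
    disc = (y - cy) ** 2 + (x - cx) ** 2 <= radius_voxels**2
    m = np.zeros(shape, bool)
    m[z0:z1] = disc[None]
    return m


def digital_ball_mask(shape, center, radius_voxels):
    z, y, x = np.mgrid[: shape[0], : shape[1], : shape[2]]
    cz, cy, cx = center
    return (z - cz) ** 2 + (y - cy) ** 2 + (x - cx) ** 2 <= radius_voxels**2
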