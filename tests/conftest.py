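import numpy as np
import pytest

from microperm.grid import LabelVolume, VoxelGrid


def cylinder_labels(
    grid: VoxelGrid, radius_um: float, length_um: float, x_start_um: float | None = None
) -> LabelVolume:
    """Axis-aligned (along x) flat-capped cylinder, centred in z/y."""
    dz, dy, dx = grid.voxel_size_um
    nz, ny, nx = grid.shape
    z = (np.arange(nz)[:, None, None] + 0.5) * dz
    y = (np.arange(ny)[None, :, None] + 0.5) * dy
    x = (np.arange(nx)[None, None, :] + 0.5) * dx
    cz, cy = nz * dz / 2, ny * dy / 2
    if x_start_um is None:
        x_start_um = (nx * dx - length_um) / 2
    mask = (
        (x >= x_start_um)
        & (x <= x_start_um + length_um)
        & (((y - cy) ** 2 + (z - cz) ** 2) <= radius_um**2)
    )
    mask = np.broadcast_to(mask, grid.shape).copy()
    return LabelVolume(labels=mask, grid=grid)


def sphere_labels(grid: VoxelGrid, radius_um: float) -> LabelVolume:
    dz, dy, dx = grid.voxel_size_um
    nz, ny, nx = grid.shape
    z = (np.arange(nz)[:, None, None] + 0.5) * dz
    y = (np.arange(ny)[None, :, None] + 0.5) * dy
    x = (np.arange(nx)[None, None, :] + 0.5) * dx
    c = (nz * dz / 2, ny * dy / 2, nx * dx / 2)
    mask = ((z - c[0]) ** 2 + (y - c[1]) ** 2 + (x - c[2]) ** 2) <= radius_um**2
    return LabelVolume(labels=np.broadcast_to(mask, grid.shape).copy(), grid=grid)


@pytest.fixture(scope="session")
def aniso_grid() -> VoxelGrid:
    """Desk-scale stand-in for the 512×512 confocal acquisition geometry."""
    return VoxelGrid(shape=(24, 96, 96), voxel_size_um=(1.0, 0.62, 0.62))


@pytest.fixture(scope="session")
def cylinder_grid() -> VoxelGrid:
    return VoxelGrid(shape=(60, 80, 200), voxel_size_um=(1.0, 0.62, 0.62))


@pytest.fixture(scope="session")
def branched_phantom(aniso_grid):
    """Random 6-branch phantom with quadrature-oracle geometry (seed 7)."""
    from microperm.synth import make_vessel_phantom

    return make_vessel_phantom(
        seed=7, grid=aniso_grid, n_branches=6, radius_range_um=(4.0, 8.0)
    )


def dice(a: np.ndarray, b: np.ndarray) -> float:
    return 2.0 * (a & b).sum() / (a.sum() + b.sum())
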