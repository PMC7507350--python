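"""Synthetic branched vessel phantoms with analytic geometry oracles.

A phantom is a union of flat-capped cylindrical segments embedded in a gel
volume.  Rasterisation uses voxel-centre membership (a voxel is vascular iff
its centre lies inside any segment), so geometry tolerances in tests are
well defined.  Ground-truth surface area and volume of the segment union are
computed by dense quadrature independent of the raster:

* volume — super-sampled membership counting (>= 5 sample points per voxel
  per axis);
* surface area — per-segment surface quadrature (lateral sheet plus end
  caps) discarding quadrature points that fall strictly inside any other
  segment.  For a single segment the quadrature weights sum to the closed
  form exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..grid import LabelVolume, VoxelGrid

__all__ = [
    "VesselSegment",
    "VesselPhantom",
    "PhantomGeometry",
    "DegeneratePhantomError",
    "make_vessel_phantom",
    "rasterize_phantom",
    "phantom_volume_oracle",
    "phantom_surface_oracle",
]


class DegeneratePhantomError(ValueError):
    """Grid too small to contain any resolvable vessel segment."""


@dataclass(frozen=True)
class VesselSegment:
    """Flat-capped cylinder from ``a_um`` to ``b_um`` with radius ``radius_um``."""

    a_um: tuple[float, float, float]
    b_um: tuple[float, float, float]
    radius_um: float

    def __post_init__(self) -> None:
        if self.radius_um <= 0:
            raise ValueError("segment radius must be positive")
        if np.allclose(self.a_um, self.b_um):
            raise ValueError("segment endpoints coincide")

    @property
    def length_um(self) -> float:
        return float(np.linalg.norm(np.subtract(self.b_um, self.a_um)))

    def axis(self) -> np.ndarray:
        d = np.subtract(self.b_um, self.a_um)
        return d / np.linalg.norm(d)

    def contains(self, pts: np.ndarray, shrink: float = 0.0) -> np.ndarray:
        """Membership test for an (..., 3) array of (z, y, x) points in μm.

        ``shrink`` > 0 tests against a slightly smaller cylinder ("strictly
        inside"), used when deciding surface-point occlusion.
        """
        a = np.asarray(self.a_um, dtype=float)
        u = self.axis()
        L = self.length_um
        rel = pts - a
        t = rel @ u
        radial2 = np.einsum("...i,...i->...", rel, rel) - t * t
        r = self.radius_um - shrink
        return (t >= shrink) & (t <= L - shrink) & (radial2 <= r * r)


@dataclass
class VesselPhantom:
    """A set of vessel segments plus the grid they live in."""

    segments: list[VesselSegment]
    grid: VoxelGrid
    seed: int

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("phantom must contain at least one segment")
        max_spacing = max(self.grid.voxel_size_um)
        for s in self.segments:
            if s.radius_um <= max_spacing:
                raise ValueError(
                    f"segment radius {s.radius_um} μm not resolvable on grid with "
                    f"max spacing {max_spacing} μm"
                )

    def contains(self, pts: np.ndarray) -> np.ndarray:
        inside = np.zeros(pts.shape[:-1], dtype=bool)
        for s in self.segments:
            inside |= s.contains(pts)
        return inside


@dataclass(frozen=True)
class PhantomGeometry:
    """Analytic (quadrature-oracle) geometry of a phantom's segment union."""

    SA_true_um2: float
    Vv_true_um3: float
    Vm_true_um3: float


def _voxel_center_points(grid: VoxelGrid, z_slice: slice) -> np.ndarray:
    dz, dy, dx = grid.voxel_size_um
    nz, ny, nx = grid.shape
    zs = (np.arange(nz)[z_slice] + 0.5) * dz
    ys = (np.arange(ny) + 0.5) * dy
    xs = (np.arange(nx) + 0.5) * dx
    Z, Y, X = np.meshgrid(zs, ys, xs, indexing="ij")
    return np.stack([Z, Y, X], axis=-1)


def rasterize_phantom(phantom: VesselPhantom) -> LabelVolume:
    """Voxel-centre rasterisation of the segment union; deterministic."""
    grid = phantom.grid
    nz = grid.shape[0]
    labels = np.zeros(grid.shape, dtype=bool)
    # z-slab chunks bound peak memory on large grids
    step = max(1, int(4e6 // (grid.shape[1] * grid.shape[2] + 1)))
    for z0 in range(0, nz, step):
        sl = slice(z0, min(z0 + step, nz))
        pts = _voxel_center_points(grid, sl)
        labels[sl] = phantom.contains(pts)
    return LabelVolume(labels=labels, grid=grid, provenance="ground_truth")


def phantom_volume_oracle(phantom: VesselPhantom, supersample: int = 5) -> float:
    """Union volume (μm³) by super-sampled membership quadrature.

    Samples ``supersample`` points per voxel per axis at sub-voxel centres;
    the estimate is the inside fraction times the grid volume.
    """
    if supersample < 5:
        raise ValueError("supersample must be >= 5 for the documented oracle")
    grid = phantom.grid
    nz, ny, nx = grid.shape
    dz, dy, dx = grid.voxel_size_um
    ss = supersample
    fine = VoxelGrid(
        shape=(nz * ss, max(ny * ss, 8), max(nx * ss, 8)),
        voxel_size_um=(dz / ss, dy / ss, dx / ss),
    )
    count = 0
    step = max(1, int(8e6 // (fine.shape[1] * fine.shape[2] + 1)))
    for z0 in range(0, fine.shape[0], step):
        sl = slice(z0, min(z0 + step, fine.shape[0]))
        pts = _voxel_center_points(fine, sl)
        count += int(phantom.contains(pts).sum())
    return count * fine.voxel_volume_um3


def _segment_surface_quadrature(
    seg: VesselSegment, pts_per_um: float = 4.0, n_theta: int = 256, n_rad: int = 48
) -> tuple[np.ndarray, np.ndarray]:
    """Quadrature points and area weights for one segment's surface.

    Weights are exact: the lateral weights sum to 2πrL and each cap's to πr²
    at any resolution.
    """
    a = np.asarray(seg.a_um, dtype=float)
    u = seg.axis()
    L, r = seg.length_um, seg.radius_um
    # orthonormal frame (u, e1, e2)
    ref = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(u, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)

    theta = (np.arange(n_theta) + 0.5) * (2 * np.pi / n_theta)
    ring = np.outer(np.cos(theta), e1) + np.outer(np.sin(theta), e2)  # (n_theta, 3)

    # lateral sheet
    n_ax = max(2, int(np.ceil(L * pts_per_um)))
    t_ax = (np.arange(n_ax) + 0.5) * (L / n_ax)
    lat_pts = (a + np.multiply.outer(t_ax, u))[:, None, :] + r * ring[None, :, :]
    lat_w = np.full(n_ax * n_theta, 2 * np.pi * r * L / (n_ax * n_theta))

    # end caps: annular rings with exact annulus-area weights
    edges = np.linspace(0.0, r, n_rad + 1)
    mid = 0.5 * (edges[:-1] + edges[1:])
    ring_area = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2) / n_theta
    cap_offsets = mid[:, None, None] * ring[None, :, :]  # (n_rad, n_theta, 3)
    cap_w_one = np.repeat(ring_area, n_theta)
    caps_pts = np.concatenate(
        [(a + cap_offsets).reshape(-1, 3), (a + L * u + cap_offsets).reshape(-1, 3)]
    )
    caps_w = np.concatenate([cap_w_one, cap_w_one])

    pts = np.concatenate([lat_pts.reshape(-1, 3), caps_pts])
    w = np.concatenate([lat_w, caps_w])
    return pts, w


def phantom_surface_oracle(phantom: VesselPhantom, pts_per_um: float = 4.0) -> float:
    """Union surface area (μm²): per-segment quadrature minus occluded points."""
    total = 0.0
    eps = 1e-9
    for i, seg in enumerate(phantom.segments):
        pts, w = _segment_surface_quadrature(seg, pts_per_um=pts_per_um)
        occluded = np.zeros(len(pts), dtype=bool)
        for j, other in enumerate(phantom.segments):
            if j == i:
                continue
            occluded |= other.contains(pts, shrink=eps)
        total += float(w[~occluded].sum())
    return total


def phantom_geometry(phantom: VesselPhantom, supersample: int = 5) -> PhantomGeometry:
    """Analytic-oracle SA/volume of the phantom plus the matrix complement."""
    Vv = phantom_volume_oracle(phantom, supersample=supersample)
    SA = phantom_surface_oracle(phantom)
    return PhantomGeometry(
        SA_true_um2=SA,
        Vv_true_um3=Vv,
        Vm_true_um3=phantom.grid.volume_um3 - Vv,
    )


def make_vessel_phantom(
    seed: int,
    grid: VoxelGrid,
    n_branches: int = 6,
    radius_range_um: tuple[float, float] = (5.0, 10.0),
    supersample: int = 5,
    oracle: bool = True,
) -> tuple[VesselPhantom, LabelVolume, PhantomGeometry | None]:
    """Generate a random branched vessel network fully interior to the grid.

    A trunk runs roughly along x with ``n_branches - 1`` child segments
    sprouting from random points on existing segments.  All segments are kept
    at least one radius inside the grid so the surface oracle needs no
    boundary clipping.  Deterministic for a fixed ``(seed, parameters)``.

    Returns the phantom, its voxel-centre rasterisation, and quadrature-oracle
    geometry (SA, vascular volume, matrix volume); pass ``oracle=False`` to
    skip the (dense) quadrature when only the raster is needed.
    """
    if n_branches < 1:
        raise ValueError("n_branches must be >= 1")
    r_lo, r_hi = radius_range_um
    if not (0 < r_lo <= r_hi):
        raise ValueError("invalid radius_range_um")
    if r_lo <= max(grid.voxel_size_um):
        raise ValueError(
            "radii must exceed the largest voxel spacing to be resolvable"
        )
    rng = np.random.default_rng(seed)
    ez, ey, ex = grid.extent_um
    margin = r_hi + max(grid.voxel_size_um)
    if ex - 2 * margin <= 2 * r_hi or ey - 2 * margin <= 0 or ez - 2 * margin <= 0:
        raise DegeneratePhantomError(
            f"grid extent {grid.extent_um} μm cannot contain a segment of "
            f"radius {r_hi} μm with the required interior margin"
        )

    def clamp(p: np.ndarray) -> np.ndarray:
        return np.clip(p, margin, np.array([ez, ey, ex]) - margin)

    segments: list[VesselSegment] = []
    # trunk along x through the mid-plane, jittered
    r0 = float(rng.uniform(r_lo, r_hi))
    z0 = float(rng.uniform(0.35, 0.65) * ez)
    y0 = float(rng.uniform(0.35, 0.65) * ey)
    a = clamp(np.array([z0, y0, margin]))
    b = clamp(np.array([z0 + rng.normal(0, 0.05 * ez), y0 + rng.normal(0, 0.05 * ey), ex - margin]))
    segments.append(VesselSegment(tuple(a), tuple(b), r0))

    for _ in range(n_branches - 1):
        parent = segments[rng.integers(len(segments))]
        t = float(rng.uniform(0.2, 0.8))
        root = np.asarray(parent.a_um) + t * (
            np.asarray(parent.b_um) - np.asarray(parent.a_um)
        )
        for _attempt in range(20):
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            length = float(rng.uniform(0.25, 0.6) * min(ey, ex))
            tip = clamp(root + length * direction)
            if np.linalg.norm(tip - root) > 2 * r_hi:
                break
        radius = float(rng.uniform(r_lo, min(r_hi, parent.radius_um)))
        segments.append(VesselSegment(tuple(root), tuple(tip), radius))

    phantom = VesselPhantom(segments=segments, grid=grid, seed=seed)
    labels = rasterize_phantom(phantom)
    geometry = phantom_geometry(phantom, supersample=supersample) if oracle else None
    return phantom, labels, geometry
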