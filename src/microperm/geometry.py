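"""Geometry measurement of a segmented vascular network.

Vascular volume Vv and matrix volume Vm are voxel counts times the voxel
volume; by construction Vv + Vm partitions the ROI volume exactly (unless a
perivascular border shell is explicitly excluded).  Surface area has two
estimators:

``mesh`` (default)
    Marching-cubes isosurface at level 0.5 on the physically-spaced lattice.
    The binary mask is padded by one voxel (so surfaces touching the ROI
    boundary are closed) and pre-smoothed with a Gaussian of 0.75 voxels per
    axis; without the smooth, the staircase isosurface of a binary tube
    over-estimates its area by 6–9%, with it cylinder and sphere phantoms
    land within ~2% of closed forms across anisotropies.

``voxel_faces``
    Sum of exposed voxel-face areas (anisotropy-aware).  Over-estimates
    smooth surfaces (the Manhattan limit) and is provided as an independent
    cross-check, and as the consistent SA basis for face-flux simulations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure as skmeasure

from .grid import LabelVolume, RoiBox, VoxelGrid

__all__ = ["GeometryMeasures", "GeometryError", "measure_geometry", "vessel_matrix_masks"]

MESH_SMOOTH_SIGMA_VOX = 0.75


class GeometryError(ValueError):
    """Degenerate ROI: no vascular or no matrix voxels."""


@dataclass(frozen=True)
class GeometryMeasures:
    """SA and compartment volumes of a segmented network within an ROI."""

    SA_um2: float
    Vv_um3: float
    Vm_um3: float
    method_tags: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.SA_um2 <= 0 or self.Vv_um3 <= 0 or self.Vm_um3 <= 0:
            raise GeometryError(
                f"geometry measures must be positive: SA={self.SA_um2}, "
                f"Vv={self.Vv_um3}, Vm={self.Vm_um3}"
            )


def mesh_surface_area(mask: np.ndarray, voxel_size_um: tuple[float, float, float]) -> float:
    """Isosurface area of a binary mask (padded, smoothed marching cubes)."""
    padded = np.pad(mask.astype(np.float32), 1)
    smoothed = ndimage.gaussian_filter(padded, sigma=MESH_SMOOTH_SIGMA_VOX)
    verts, faces, _, _ = skmeasure.marching_cubes(
        smoothed, level=0.5, spacing=voxel_size_um
    )
    return float(skmeasure.mesh_surface_area(verts, faces))


def voxel_face_area(mask: np.ndarray, voxel_size_um: tuple[float, float, float]) -> float:
    """Total area of vascular voxel faces exposed to matrix or the boundary."""
    dz, dy, dx = voxel_size_um
    face_areas = (dy * dx, dz * dx, dz * dy)  # faces normal to z, y, x
    total = 0.0
    m = mask.astype(np.int8)
    for axis, fa in enumerate(face_areas):
        diff = np.diff(m, axis=axis)
        internal = np.abs(diff).sum()  # vascular/matrix interfaces
        first = np.take(m, 0, axis=axis).sum()
        last = np.take(m, -1, axis=axis).sum()
        total += fa * float(internal + first + last)
    return total


def perivascular_shell(
    mask: np.ndarray, voxel_size_um: tuple[float, float, float], shell_um: float
) -> np.ndarray:
    """Matrix voxels within ``shell_um`` of the vascular surface."""
    if shell_um <= 0:
        return np.zeros_like(mask, dtype=bool)
    dist = ndimage.distance_transform_edt(~mask, sampling=voxel_size_um)
    return (~mask) & (dist <= shell_um)


def vessel_matrix_masks(
    labels: LabelVolume,
    roi_box: RoiBox | None = None,
    border_shell_um: float = 0.0,
) -> tuple[np.ndarray, np.ndarray, RoiBox]:
    """Cropped vascular and matrix masks, honouring an optional border shell.

    The shell (matrix voxels within ``border_shell_um`` of the vessel wall)
    is excluded from the matrix mask — an option for avoiding PSF /
    partial-volume bleed next to the wall.
    """
    box = labels.grid.check_box(roi_box) if roi_box is not None else labels.box_or_full()
    vasc = labels.crop(box)
    matrix = ~vasc
    if border_shell_um > 0:
        matrix &= ~perivascular_shell(vasc, labels.grid.voxel_size_um, border_shell_um)
    return vasc, matrix, box


def measure_geometry(
    labels: LabelVolume,
    sa_method: str = "mesh",
    roi_box: RoiBox | None = None,
    border_shell_um: float = 0.0,
) -> GeometryMeasures:
    """Measure SA, vascular volume and matrix volume within an ROI.

    Raises :class:`GeometryError` on an all-vascular or all-matrix ROI.
    """
    if sa_method not in ("mesh", "voxel_faces"):
        raise ValueError(f"unknown sa_method {sa_method!r}")
    vasc, matrix, box = vessel_matrix_masks(labels, roi_box, border_shell_um)
    n_vasc = int(vasc.sum())
    n_matrix = int(matrix.sum())
    if n_vasc == 0:
        raise GeometryError("ROI contains no vascular voxels")
    if n_matrix == 0:
        raise GeometryError("ROI contains no matrix voxels")
    vox = labels.grid.voxel_volume_um3
    spacing = labels.grid.voxel_size_um
    if sa_method == "mesh":
        sa = mesh_surface_area(vasc, spacing)
    else:
        sa = voxel_face_area(vasc, spacing)
    tags = [f"sa:{sa_method}", f"border_shell_um:{border_shell_um:g}"]
    return GeometryMeasures(
        SA_um2=sa,
        Vv_um3=n_vasc * vox,
        Vm_um3=n_matrix * vox,
        method_tags=tuple(tags),
    )
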