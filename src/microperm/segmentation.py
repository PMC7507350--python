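"""Vessel segmentation and adherent-cell counting.

The vascular compartment is segmented from the first-timepoint tracer stack
by deterministic global thresholding (Otsu on a 256-bin histogram, or a
user-fixed threshold), anisotropy-aware morphological closing, and removal
of small connected components.  All physical parameters are in μm and are
converted per-axis to voxels, never applied as raw voxel radii.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .grid import LabelVolume, VoxelGrid

__all__ = [
    "NoVasculatureError",
    "AdhesionCount",
    "segment_vessels",
    "count_adherent_cells",
    "anisotropic_ball",
]

OTSU_NBINS = 256
#: 26-connectivity structuring element for 3-D component labelling
CONNECTIVITY_26 = np.ones((3, 3, 3), dtype=bool)


class NoVasculatureError(ValueError):
    """Raised when segmentation yields no vascular voxels (never a silent zero)."""


def anisotropic_ball(radius_um: float, voxel_size_um: tuple[float, float, float]) -> np.ndarray:
    """Boolean ellipsoid covering a physical ball of ``radius_um``.

    Semi-axes in voxels are radius divided by each spacing, so the element is
    flattened along coarsely-sampled axes.
    """
    half = [max(int(np.floor(radius_um / s)), 0) for s in voxel_size_um]
    grids = np.meshgrid(
        *[np.arange(-h, h + 1) * s for h, s in zip(half, voxel_size_um)],
        indexing="ij",
        sparse=True,
    )
    dist2 = sum(g**2 for g in grids)
    return dist2 <= radius_um**2


def _remove_small(mask: np.ndarray, min_voxels: int) -> np.ndarray:
    if min_voxels <= 1:
        return mask
    lab, n = ndimage.label(mask, structure=CONNECTIVITY_26)
    if n == 0:
        return mask
    sizes = np.bincount(lab.ravel())
    keep = sizes >= min_voxels
    keep[0] = False
    return keep[lab]


def segment_vessels(
    stack_t1: np.ndarray,
    grid: VoxelGrid,
    method: str = "otsu",
    threshold: float | None = None,
    min_object_um3: float = 0.0,
    closing_radius_um: float = 0.0,
) -> LabelVolume:
    """Segment vascular voxels from the t1 tracer stack.

    Parameters
    ----------
    method
        ``"otsu"`` (global Otsu threshold on a 256-bin histogram of the full
        stack) or ``"fixed_threshold"`` (requires ``threshold``).
    min_object_um3
        Connected components (26-connectivity) smaller than this physical
        volume are discarded.
    closing_radius_um
        Physical radius of the morphological closing applied to bridge small
        gaps; 0 disables it.

    Raises
    ------
    NoVasculatureError
        If the stack is constant or the mask is empty after filtering.
    """
    stack = np.asarray(stack_t1)
    if stack.shape != grid.shape:
        raise ValueError(f"stack shape {stack.shape} != grid shape {grid.shape}")
    if method == "otsu":
        if np.ptp(stack) == 0:
            raise NoVasculatureError(
                "no vasculature detected: stack intensity is constant"
            )
        thr = float(threshold_otsu(stack, nbins=OTSU_NBINS))
    elif method == "fixed_threshold":
        if threshold is None:
            raise ValueError("fixed_threshold method requires a threshold")
        thr = float(threshold)
    else:
        raise ValueError(f"unknown segmentation method {method!r}")

    mask = stack > thr
    if closing_radius_um > 0:
        selem = anisotropic_ball(closing_radius_um, grid.voxel_size_um)
        if selem.sum() > 1:
            mask = ndimage.binary_closing(mask, structure=selem)
    if min_object_um3 > 0:
        min_vox = int(np.ceil(min_object_um3 / grid.voxel_volume_um3))
        mask = _remove_small(mask, min_vox)
    if not mask.any():
        raise NoVasculatureError(
            f"no vasculature detected after thresholding at {thr:g} and filtering"
        )
    tags = [f"threshold:{method}:{thr:g}"]
    if closing_radius_um > 0:
        tags.append(f"closing_um:{closing_radius_um:g}")
    if min_object_um3 > 0:
        tags.append(f"min_object_um3:{min_object_um3:g}")
    return LabelVolume(labels=mask, grid=grid, provenance="segmented", method_tags=tags)


@dataclass(frozen=True)
class AdhesionCount:
    """Count of cells adherent to the vessel wall within an ROI."""

    n_cells: int
    roi_id: str
    min_volume_um3: float

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")


def count_adherent_cells(
    cell_stack: np.ndarray,
    vessel_mask: LabelVolume,
    threshold: float,
    min_volume_um3: float,
    max_gap_um: float,
    roi_id: str = "roi0",
) -> AdhesionCount:
    """Count thresholded cell-channel blobs adherent to the vasculature.

    A component (26-connected, above ``min_volume_um3``) counts as adherent
    when any of its voxels lies within ``max_gap_um`` of the vessel surface —
    equivalent to intersecting the vessel mask dilated by that physical
    distance.
    """
    cells = np.asarray(cell_stack)
    if cells.shape != vessel_mask.grid.shape:
        raise ValueError(
            f"cell stack shape {cells.shape} != grid shape {vessel_mask.grid.shape}"
        )
    spacing = vessel_mask.grid.voxel_size_um
    mask = cells > threshold
    lab, n = ndimage.label(mask, structure=CONNECTIVITY_26)
    if n == 0:
        return AdhesionCount(0, roi_id, min_volume_um3)
    min_vox = max(1, int(np.ceil(min_volume_um3 / vessel_mask.grid.voxel_volume_um3)))
    sizes = np.bincount(lab.ravel())
    dist_to_vessel = ndimage.distance_transform_edt(
        ~vessel_mask.labels, sampling=spacing
    )
    n_adherent = 0
    for comp in range(1, n + 1):
        if sizes[comp] < min_vox:
            continue
        if float(dist_to_vessel[lab == comp].min()) <= max_gap_um:
            n_adherent += 1
    return AdhesionCount(n_adherent, roi_id, min_volume_um3)
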