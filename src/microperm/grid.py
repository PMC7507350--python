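"""Voxel lattices and compartment label volumes.

Conventions used throughout the package:

* axis order is ``(z, y, x)``, 0-based;
* physical units are micrometres (μm) for lengths, seconds for times;
* ROI boxes are half-open integer index boxes ``(z0, z1, y0, y1, x0, x1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = ["VoxelGrid", "LabelVolume", "RoiBox"]

#: half-open index box (z0, z1, y0, y1, x0, x1)
RoiBox = tuple[int, int, int, int, int, int]

_MIN_DIM = 8


@dataclass(frozen=True)
class VoxelGrid:
    """A 3-D voxel lattice with physical spacing.

    Parameters
    ----------
    shape
        ``(nz, ny, nx)`` voxel counts; every dimension must be >= 8.
    voxel_size_um
        ``(dz, dy, dx)`` spacing in μm; all strictly positive.  Confocal
        stacks are typically anisotropic (dz > dx); the anisotropy ratio
        dz/dx is exposed as :attr:`anisotropy`.
    """

    shape: tuple[int, int, int]
    voxel_size_um: tuple[float, float, float]

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or len(self.voxel_size_um) != 3:
            raise ValueError("shape and voxel_size_um must be length-3 tuples")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(
            self, "voxel_size_um", tuple(float(s) for s in self.voxel_size_um)
        )
        nz, ny, nx = self.shape
        # nz = 1 permitted so single-slice TIFFs can be loaded; in-plane dims
        # below 8 are always degenerate for this pipeline
        if nz < 1 or ny < _MIN_DIM or nx < _MIN_DIM:
            raise ValueError(
                f"grid dimensions must be >= (1, {_MIN_DIM}, {_MIN_DIM}), got {self.shape}"
            )
        if any(not np.isfinite(s) or s <= 0 for s in self.voxel_size_um):
            raise ValueError(f"voxel spacings must be positive finite, got {self.voxel_size_um}")

    @property
    def anisotropy(self) -> float:
        """dz/dx ratio (1.0 for isotropic grids)."""
        return self.voxel_size_um[0] / self.voxel_size_um[2]

    @property
    def voxel_volume_um3(self) -> float:
        dz, dy, dx = self.voxel_size_um
        return dz * dy * dx

    @property
    def extent_um(self) -> tuple[float, float, float]:
        """Physical size of the imaged volume along (z, y, x)."""
        return tuple(n * s for n, s in zip(self.shape, self.voxel_size_um))

    @property
    def volume_um3(self) -> float:
        return float(np.prod(self.extent_um))

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Open-grid physical coordinates of voxel centres, broadcastable to shape."""
        axes = [
            (np.arange(n) + 0.5) * s for n, s in zip(self.shape, self.voxel_size_um)
        ]
        return tuple(np.meshgrid(*axes, indexing="ij", sparse=True))

    def full_box(self) -> RoiBox:
        nz, ny, nx = self.shape
        return (0, nz, 0, ny, 0, nx)

    def check_box(self, box: RoiBox) -> RoiBox:
        box = tuple(int(b) for b in box)
        if len(box) != 6:
            raise ValueError("ROI box must be (z0, z1, y0, y1, x0, x1)")
        for lo, hi, n in zip(box[0::2], box[1::2], self.shape):
            if not (0 <= lo < hi <= n):
                raise ValueError(f"ROI box {box} out of bounds for grid shape {self.shape}")
        return box


@dataclass
class LabelVolume:
    """Binary vascular/matrix compartment labels on a :class:`VoxelGrid`.

    ``labels`` is boolean with vascular voxels True (1) and matrix False (0).
    ``provenance`` records whether the mask came from a synthetic ground truth
    or from segmentation; a segmented mask with no vascular voxel is rejected
    upstream by :func:`microperm.segmentation.segment_vessels`.
    """

    labels: np.ndarray
    grid: VoxelGrid
    provenance: Literal["ground_truth", "segmented"] = "ground_truth"
    roi_box: RoiBox | None = None
    method_tags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels).astype(bool)
        if self.labels.shape != self.grid.shape:
            raise ValueError(
                f"labels shape {self.labels.shape} != grid shape {self.grid.shape}"
            )
        if self.roi_box is not None:
            self.roi_box = self.grid.check_box(self.roi_box)

    def box_or_full(self) -> RoiBox:
        return self.roi_box if self.roi_box is not None else self.grid.full_box()

    def crop(self, box: RoiBox) -> np.ndarray:
        z0, z1, y0, y1, x0, x1 = self.grid.check_box(box)
        return self.labels[z0:z1, y0:y1, x0:x1]

    @property
    def n_vascular(self) -> int:
        return int(self.labels.sum())


def crop_stack(stack: np.ndarray, box: RoiBox) -> np.ndarray:
    """Crop an intensity stack to a half-open (z, y, x) box."""
    z0, z1, y0, y1, x0, x1 = box
    return stack[z0:z1, y0:y1, x0:x1]
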