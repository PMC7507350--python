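"""Microvascular permeability from two-timepoint tracer stacks.

The permeability coefficient of the vessel wall is estimated from the rise
of mean extravascular (matrix) fluorescence between two acquisitions:

    P = (Vm / (SA · ΔI)) · (ΔIm / Δt)

with ΔIm = Im,2 − Im,1 the increase in mean matrix intensity over the
interval Δt, ΔI = Iv,1 − Im,1 the vessel–matrix intensity contrast at the
start of the measurement, Vm the matrix volume and SA the vessel surface
area.  Iv is measured at the first timepoint only.  P is reported natively
in μm/s and in cm/s (×1e-4) for comparability with the transport
literature.

The estimator is offset-sensitive: adding a constant background b to both
stacks leaves ΔIm unchanged but inflates ΔI, biasing P downward — hence the
optional constant background subtraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import GeometryMeasures, measure_geometry, vessel_matrix_masks
from .grid import LabelVolume, RoiBox, VoxelGrid, crop_stack
from .synth.tracer import TracerStackPair

__all__ = [
    "PermeabilityResult",
    "RoiSamplingPlan",
    "RoiAggregate",
    "TracerEquilibratedError",
    "estimate_permeability",
    "sample_rois",
    "aggregate_rois",
]


class TracerEquilibratedError(ValueError):
    """Initial vessel–matrix contrast ΔI <= 0: P is undefined."""


@dataclass(frozen=True)
class PermeabilityResult:
    """P with every intermediate retained for auditability."""

    P_um_per_s: float
    Iv1: float
    Im1: float
    Im2: float
    dt_s: float
    geometry: GeometryMeasures
    roi_id: str = "roi0"
    warnings: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.dt_s <= 0:
            raise ValueError("dt_s must be positive")
        if self.dI <= 0:
            raise TracerEquilibratedError("dI must be positive")
        expected = (self.geometry.Vm_um3 / (self.geometry.SA_um2 * self.dI)) * (
            self.dIm / self.dt_s
        )
        scale = max(abs(expected), abs(self.P_um_per_s), 1e-300)
        if abs(expected - self.P_um_per_s) / scale > 1e-12:
            raise ValueError("P inconsistent with its intermediates")

    @property
    def dIm(self) -> float:
        return self.Im2 - self.Im1

    @property
    def dI(self) -> float:
        return self.Iv1 - self.Im1

    @property
    def P_cm_per_s(self) -> float:
        return self.P_um_per_s * 1e-4

    def to_dict(self) -> dict:
        return {
            "roi_id": self.roi_id,
            "P_um_per_s": self.P_um_per_s,
            "P_cm_per_s": self.P_cm_per_s,
            "Iv1": self.Iv1,
            "Im1": self.Im1,
            "Im2": self.Im2,
            "dI": self.dI,
            "dIm": self.dIm,
            "dt_s": self.dt_s,
            "SA_um2": self.geometry.SA_um2,
            "Vv_um3": self.geometry.Vv_um3,
            "Vm_um3": self.geometry.Vm_um3,
            "method_tags": list(self.geometry.method_tags),
            "warnings": list(self.warnings),
        }


def estimate_permeability(
    pair: TracerStackPair,
    labels: LabelVolume,
    geometry: GeometryMeasures | None = None,
    roi_box: RoiBox | None = None,
    border_shell_um: float = 0.0,
    background: float = 0.0,
    sa_method: str = "mesh",
    roi_id: str = "roi0",
) -> PermeabilityResult:
    """Estimate P for one ROI.

    ``geometry`` may be supplied (e.g. ground truth, or a cached
    measurement); otherwise it is measured from ``labels`` over the same ROI
    with the same border shell.  ``background`` is a constant offset
    subtracted from both stacks before averaging (off by default).

    Raises :class:`TracerEquilibratedError` when Im1 >= Iv1; a negative ΔIm
    (photobleaching or noise) is allowed but tagged in ``warnings``.
    """
    if pair.grid.shape != labels.grid.shape:
        raise ValueError("stack pair and labels live on different grids")
    vasc, matrix, box = vessel_matrix_masks(labels, roi_box, border_shell_um)
    if not vasc.any() or not matrix.any():
        raise ValueError("ROI must contain both vascular and matrix voxels")
    s1 = crop_stack(pair.stack_t1, box) - background
    s2 = crop_stack(pair.stack_t2, box) - background
    Iv1 = float(s1[vasc].mean())
    Im1 = float(s1[matrix].mean())
    Im2 = float(s2[matrix].mean())
    dI = Iv1 - Im1
    if dI <= 0:
        raise TracerEquilibratedError(
            f"tracer equilibrated or inverted contrast: Iv1={Iv1:g} <= Im1={Im1:g}"
        )
    if geometry is None:
        geometry = measure_geometry(
            labels, sa_method=sa_method, roi_box=box, border_shell_um=border_shell_um
        )
    dIm = Im2 - Im1
    warnings = ()
    if dIm < 0:
        warnings = ("negative_dIm: matrix intensity decreased (photobleaching or noise); P is negative",)
    P = (geometry.Vm_um3 / (geometry.SA_um2 * dI)) * (dIm / pair.dt_s)
    return PermeabilityResult(
        P_um_per_s=P,
        Iv1=Iv1,
        Im1=Im1,
        Im2=Im2,
        dt_s=pair.dt_s,
        geometry=geometry,
        roi_id=roi_id,
        warnings=warnings,
    )


@dataclass(frozen=True)
class RoiSamplingPlan:
    """Randomly placed ROI boxes emulating unbiased sampling along the gel."""

    n_rois: int
    roi_size_um: tuple[float, float, float]
    seed: int
    boxes: tuple[RoiBox, ...]
    warnings: tuple[str, ...] = ()


def sample_rois(
    grid: VoxelGrid,
    roi_size_um: tuple[float, float, float],
    n_rois: int = 3,
    seed: int = 0,
) -> RoiSamplingPlan:
    """Place ``n_rois`` axis-aligned boxes uniformly at random (seeded).

    ROI sizes are given in μm and converted per-axis; a size equal to the
    grid extent forces a single placement.  Overlapping boxes are allowed
    but logged in ``warnings``.
    """
    if n_rois < 1:
        raise ValueError("n_rois must be >= 1")
    sizes_vox = []
    for size_um, spacing, n in zip(roi_size_um, grid.voxel_size_um, grid.shape):
        sv = int(round(size_um / spacing))
        if sv < 1:
            raise ValueError(f"ROI size {size_um} μm below one voxel ({spacing} μm)")
        if sv > n:
            raise ValueError(
                f"ROI size {size_um} μm exceeds grid extent along an axis ({n * spacing} μm)"
            )
        sizes_vox.append(sv)
    rng = np.random.default_rng(seed)
    boxes = []
    for _ in range(n_rois):
        box = []
        for sv, n in zip(sizes_vox, grid.shape):
            origin = int(rng.integers(0, n - sv + 1))
            box.extend((origin, origin + sv))
        boxes.append(tuple(box))
    warnings = []
    for i in range(len(boxes)):
        for j in range(i + 1, len(boxes)):
            if _boxes_overlap(boxes[i], boxes[j]):
                warnings.append(f"roi{i} and roi{j} overlap")
    return RoiSamplingPlan(
        n_rois=n_rois,
        roi_size_um=tuple(float(s) for s in roi_size_um),
        seed=seed,
        boxes=tuple(boxes),
        warnings=tuple(warnings),
    )


def _boxes_overlap(a: RoiBox, b: RoiBox) -> bool:
    return all(a[2 * i] < b[2 * i + 1] and b[2 * i] < a[2 * i + 1] for i in range(3))


@dataclass(frozen=True)
class RoiAggregate:
    """Across-ROI summary: arithmetic mean and sample SD of P."""

    mean_P_um_per_s: float
    sd_P_um_per_s: float | None
    n: int
    outlier_roi_ids: tuple[str, ...] = ()
    per_roi: tuple[PermeabilityResult, ...] = ()

    def to_dict(self) -> dict:
        return {
            "mean_P_um_per_s": self.mean_P_um_per_s,
            "mean_P_cm_per_s": self.mean_P_um_per_s * 1e-4,
            "sd_P_um_per_s": self.sd_P_um_per_s,
            "n_rois": self.n,
            "outlier_roi_ids": list(self.outlier_roi_ids),
        }


def aggregate_rois(results: list[PermeabilityResult]) -> RoiAggregate:
    """Mean and sample SD of P across ROIs; flags > 3 SD deviants.

    With a single ROI the SD is reported as absent (None), never 0.
    """
    if not results:
        raise ValueError("aggregate_rois requires at least one result")
    values = np.array([r.P_um_per_s for r in results], dtype=float)
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if len(values) > 1 else None
    outliers = ()
    if sd is not None and sd > 0:
        outliers = tuple(
            r.roi_id for r, v in zip(results, values) if abs(v - mean) > 3 * sd
        )
    return RoiAggregate(
        mean_P_um_per_s=mean,
        sd_P_um_per_s=sd,
        n=len(results),
        outlier_roi_ids=outliers,
        per_roi=tuple(results),
    )
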