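"""Reproducible end-to-end pipelines with validated configuration.

Two entry points mirror the two halves of the assay:

* :func:`run_permeability_pipeline` — load the two tracer stacks, segment
  the vasculature on the first, sample random ROIs along the gel, measure
  geometry and estimate P per ROI, then aggregate.
* :func:`run_cooperativity_pipeline` — read a cytokine table (or raw
  responses plus calibrators), fit/invert the 5PL where needed, impute
  censoring, and compute log2 fold changes and the cooperativity index D.

A single config seed governs every stochastic stage; per-stage seeds are
derived deterministically from it, so a report is bit-reproducible from its
embedded config and the input files.  Reports carry no timestamps for the
same reason.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import __version__
from .cooperativity import (
    compute_cooperativity_D,
    compute_log2fc,
    fit_five_pl,
    impute_censoring,
    invert_five_pl,
)
from .geometry import measure_geometry
from .io import load_stack, read_cytokine_csv
from .permeability import aggregate_rois, estimate_permeability, sample_rois
from .segmentation import segment_vessels

__all__ = [
    "SegmentationParams",
    "RoiPlanParams",
    "CytokineParams",
    "RunConfig",
    "RunReport",
    "run_permeability_pipeline",
    "run_cooperativity_pipeline",
    "stage_seed",
]

REPORT_SCHEMA_VERSION = 1


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the run seed (< 2**31)."""
    tag = zlib.crc32(stage.encode())  # stable across processes, unlike hash()
    ss = np.random.SeedSequence([int(seed), tag])
    return int(ss.generate_state(1)[0] % (2**31))


class SegmentationParams(BaseModel):
    method: Literal["otsu", "fixed_threshold"] = "otsu"
    threshold: Optional[float] = None
    min_object_um3: float = Field(0.0, ge=0)
    closing_radius_um: float = Field(0.0, ge=0)

    @model_validator(mode="after")
    def _fixed_needs_threshold(self):
        if self.method == "fixed_threshold" and self.threshold is None:
            raise ValueError("fixed_threshold segmentation requires a threshold")
        return self


class RoiPlanParams(BaseModel):
    n_rois: int = Field(3, ge=1)
    roi_size_um: Optional[tuple[float, float, float]] = None  # None = full volume


class CytokineParams(BaseModel):
    table_path: Optional[str] = None
    responses_path: Optional[str] = None
    calibrators_path: Optional[str] = None
    tolerance: float = Field(0.05, ge=0)
    imputation: Literal["bound", "half_lloq"] = "bound"
    d_mode: Literal["condition_means", "per_replicate"] = "condition_means"
    log2fc_treatment: str = "MVN_plus_Spheroids"
    log2fc_control: str = "MVN"

    @model_validator(mode="after")
    def _one_input(self):
        if self.table_path is None and self.responses_path is None:
            raise ValueError("cytokine analysis needs table_path or responses_path")
        if self.responses_path is not None and self.calibrators_path is None:
            raise ValueError("raw responses require calibrators_path")
        return self


class RunConfig(BaseModel):
    """Validated run configuration; echoed verbatim into every report."""

    seed: int = 0
    output_dir: Optional[str] = None
    t1_path: Optional[str] = None
    t2_path: Optional[str] = None
    dt_s: Optional[float] = None
    voxel_size_um: Optional[tuple[float, float, float]] = None
    border_shell_um: float = Field(0.0, ge=0)
    sa_method: Literal["mesh", "voxel_faces"] = "mesh"
    segmentation: SegmentationParams = SegmentationParams()
    roi_plan: RoiPlanParams = RoiPlanParams()
    cytokine: Optional[CytokineParams] = None

    @model_validator(mode="after")
    def _perm_inputs(self):
        if self.dt_s is not None and self.dt_s <= 0:
            raise ValueError("dt_s must be positive")
        return self

    def require_permeability_inputs(self) -> None:
        missing = [
            name
            for name, v in (("t1_path", self.t1_path), ("t2_path", self.t2_path), ("dt_s", self.dt_s))
            if v is None
        ]
        if missing:
            raise ValueError(f"permeability pipeline config missing: {missing}")


@dataclass
class RunReport:
    """Serializable record of a pipeline run (no timestamps: reproducible)."""

    kind: str
    config: dict
    version: str = __version__
    schema_version: int = REPORT_SCHEMA_VERSION
    per_roi: list = field(default_factory=list)
    aggregate: dict | None = None
    cooperativity: list = field(default_factory=list)
    log2fc: list = field(default_factory=list)
    warnings: list = field(default_factory=list)
    errors: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "version": self.version,
            "schema_version": self.schema_version,
            "config": self.config,
            "per_roi": self.per_roi,
            "aggregate": self.aggregate,
            "cooperativity": self.cooperativity,
            "log2fc": self.log2fc,
            "warnings": self.warnings,
            "errors": self.errors,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True, **kwargs)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(self.to_json())
        return path


def run_permeability_pipeline(config: RunConfig) -> RunReport:
    """Stacks → segmentation → ROI sampling → geometry → P → aggregate."""
    config.require_permeability_inputs()
    report = RunReport(kind="permeability", config=config.model_dump(mode="json"))

    stack1, grid, w1 = load_stack(config.t1_path, config.voxel_size_um)
    stack2, grid2, w2 = load_stack(config.t2_path, config.voxel_size_um)
    report.warnings.extend(w1 + w2)
    if grid2.shape != grid.shape:
        raise ValueError(
            f"t1/t2 stack shapes differ: {grid.shape} vs {grid2.shape}"
        )

    seg = config.segmentation
    labels = segment_vessels(
        stack1,
        grid,
        method=seg.method,
        threshold=seg.threshold,
        min_object_um3=seg.min_object_um3,
        closing_radius_um=seg.closing_radius_um,
    )

    from .synth.tracer import TracerStackPair  # local import avoids cycle at module load

    pair = TracerStackPair(
        stack_t1=stack1, stack_t2=stack2, grid=grid, t1_s=0.0, t2_s=float(config.dt_s)
    )

    plan_params = config.roi_plan
    if plan_params.roi_size_um is None:
        boxes = [grid.full_box()]
        roi_warnings: tuple[str, ...] = ()
    else:
        plan = sample_rois(
            grid,
            plan_params.roi_size_um,
            n_rois=plan_params.n_rois,
            seed=stage_seed(config.seed, "roi_sampling"),
        )
        boxes = list(plan.boxes)
        roi_warnings = plan.warnings
    report.warnings.extend(roi_warnings)

    results = []
    for i, box in enumerate(boxes):
        roi_id = f"roi{i}"
        try:
            geom = measure_geometry(
                labels,
                sa_method=config.sa_method,
                roi_box=box,
                border_shell_um=config.border_shell_um,
            )
            res = estimate_permeability(
                pair,
                labels,
                geometry=geom,
                roi_box=box,
                border_shell_um=config.border_shell_um,
                roi_id=roi_id,
            )
            results.append(res)
            report.per_roi.append({**res.to_dict(), "roi_box": list(box)})
        except (ValueError, RuntimeError) as exc:
            report.errors.append(
                {"stage": "permeability", "roi_id": roi_id, "error": str(exc)}
            )
    if results:
        report.aggregate = aggregate_rois(results).to_dict()
    return report


def _concentrations_from_responses(
    responses: pd.DataFrame, calibrators: pd.DataFrame
) -> pd.DataFrame:
    """Fit a 5PL per analyte from calibrators and invert the responses."""
    rows = []
    for analyte, cal in calibrators.groupby("analyte"):
        curve = fit_five_pl(cal["concentration_pg_ml"], cal["response"])
        sub = responses[responses["analyte"] == analyte]
        for r in sub.itertuples(index=False):
            conc, flag = invert_five_pl(float(r.response), curve)
            rows.append(
                {
                    "analyte": analyte,
                    "condition": r.condition,
                    "replicate": getattr(r, "replicate", 1),
                    "concentration_pg_ml": conc,
                    "censor": flag,
                }
            )
    return pd.DataFrame(rows)


def run_cooperativity_pipeline(config: RunConfig) -> RunReport:
    """Cytokine table (or responses + calibrators) → censoring → log2FC → D."""
    if config.cytokine is None:
        raise ValueError("config.cytokine section is required")
    cyt = config.cytokine
    report = RunReport(kind="cooperativity", config=config.model_dump(mode="json"))

    if cyt.responses_path is not None:
        responses = pd.read_csv(cyt.responses_path)
        calibrators = pd.read_csv(cyt.calibrators_path)
        table = _concentrations_from_responses(responses, calibrators)
    else:
        table = read_cytokine_csv(cyt.table_path)
    table = impute_censoring(table, method=cyt.imputation)

    try:
        fc = compute_log2fc(table, cyt.log2fc_treatment, cyt.log2fc_control)
        report.log2fc = fc.to_dict(orient="records")
    except ValueError as exc:
        report.errors.append({"stage": "log2fc", "error": str(exc)})

    results = compute_cooperativity_D(table, tolerance=cyt.tolerance, mode=cyt.d_mode)
    report.cooperativity = [r.to_dict() for r in results]
    return report
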