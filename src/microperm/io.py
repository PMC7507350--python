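"""TIFF / CSV / JSON input-output with explicit voxel-size provenance.

Stacks are written as 32-bit TIFF with ImageJ-style spacing metadata and
resolution tags, plus a JSON sidecar (``<file>.json``) carrying voxel size,
acquisition times, seed and any ground truth.  On load the voxel size is
resolved in priority order: explicit override, OME/ImageJ metadata plus
resolution tags, sidecar.  A stack whose voxel size cannot be resolved is a
hard error — isotropy is never assumed silently.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .grid import VoxelGrid
from .synth.tracer import TracerStackPair

__all__ = [
    "MissingVoxelSizeError",
    "load_stack",
    "save_stack",
    "save_stack_pair",
    "save_mask",
    "read_cytokine_csv",
    "write_cytokine_csv",
]


class MissingVoxelSizeError(ValueError):
    """Voxel size absent from metadata and no override supplied."""


def save_stack(
    path: str | Path,
    stack: np.ndarray,
    grid: VoxelGrid,
    sidecar: dict | None = None,
) -> Path:
    """Write a z-stack as 32-bit TIFF with spacing metadata and a JSON sidecar."""
    path = Path(path)
    dz, dy, dx = grid.voxel_size_um
    data = np.asarray(stack, dtype=np.float32)
    if data.ndim == 2:
        data = data[None]
    tifffile.imwrite(
        path,
        data,
        imagej=True,
        resolution=(1.0 / dx, 1.0 / dy),
        metadata={"spacing": dz, "unit": "um", "axes": "ZYX"},
    )
    meta = {"voxel_size_um": [dz, dy, dx], "shape": list(data.shape)}
    if sidecar:
        meta.update(sidecar)
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))
    return path


def save_stack_pair(
    pair: TracerStackPair,
    path_t1: str | Path,
    path_t2: str | Path,
    extra: dict | None = None,
) -> tuple[Path, Path]:
    """Write the two timepoint stacks with a shared sidecar schema."""
    common = {
        "t1_s": pair.t1_s,
        "t2_s": pair.t2_s,
        "channel_name": pair.channel_name,
    }
    common.update(pair.meta)
    if extra:
        common.update(extra)
    p1 = save_stack(path_t1, pair.stack_t1, pair.grid, {**common, "timepoint": 1})
    p2 = save_stack(path_t2, pair.stack_t2, pair.grid, {**common, "timepoint": 2})
    return p1, p2


def save_mask(path: str | Path, labels: np.ndarray, grid: VoxelGrid) -> Path:
    """Write a binary mask as 8-bit TIFF (vascular = 255)."""
    path = Path(path)
    dz, dy, dx = grid.voxel_size_um
    tifffile.imwrite(
        path,
        (np.asarray(labels, dtype=bool) * np.uint8(255)),
        imagej=True,
        resolution=(1.0 / dx, 1.0 / dy),
        metadata={"spacing": dz, "unit": "um", "axes": "ZYX"},
    )
    return path


def _voxel_from_tiff(tif: tifffile.TiffFile) -> tuple[float, float, float] | None:
    dz = dy = dx = None
    # OME metadata
    if tif.ome_metadata:
        try:
            import xml.etree.ElementTree as ET

            root = ET.fromstring(tif.ome_metadata)
            ns = {"ome": root.tag.split("}")[0].strip("{")}
            px = root.find(".//ome:Pixels", ns)
            if px is not None:
                dx = px.get("PhysicalSizeX")
                dy = px.get("PhysicalSizeY")
                dz = px.get("PhysicalSizeZ")
        except Exception:
            pass
    # ImageJ spacing + resolution tags
    if dz is None and tif.imagej_metadata:
        dz = tif.imagej_metadata.get("spacing")
    if dx is None:
        page = tif.pages[0]
        xres = page.tags.get("XResolution")
        yres = page.tags.get("YResolution")
        if xres is not None and yres is not None:
            xr = xres.value[0] / xres.value[1]
            yr = yres.value[0] / yres.value[1]
            if xr > 0 and yr > 0:
                dx, dy = 1.0 / xr, 1.0 / yr
    if dz is None or dy is None or dx is None:
        return None
    return (float(dz), float(dy), float(dx))


def load_stack(
    path: str | Path,
    voxel_override: tuple[float, float, float] | None = None,
) -> tuple[np.ndarray, VoxelGrid, list[str]]:
    """Load a TIFF/OME-TIFF z-stack, resolving the voxel size.

    Returns ``(stack, grid, warnings)`` with axes normalised to (z, y, x); a
    single-slice image is accepted as nz = 1 with a warning.

    Raises :class:`MissingVoxelSizeError` when no override is given and the
    file (or its JSON sidecar) carries no voxel-size metadata.
    """
    path = Path(path)
    warnings: list[str] = []
    with tifffile.TiffFile(path) as tif:
        stack = tif.asarray()
        voxel = _voxel_from_tiff(tif)
    if stack.ndim == 2:
        stack = stack[None]
        warnings.append("single-slice TIFF accepted as nz=1")
    if stack.ndim != 3:
        raise ValueError(f"expected a 2-D or 3-D stack, got shape {stack.shape}")
    if voxel_override is not None:
        voxel = tuple(float(v) for v in voxel_override)
    elif voxel is None:
        sidecar = path.with_suffix(path.suffix + ".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            if "voxel_size_um" in meta:
                voxel = tuple(float(v) for v in meta["voxel_size_um"])
    if voxel is None:
        raise MissingVoxelSizeError(
            f"{path}: voxel size (PhysicalSizeZ/Y/X or ImageJ spacing + resolution) "
            "not found in metadata and no --voxel override given"
        )
    grid = VoxelGrid(shape=stack.shape, voxel_size_um=voxel)
    return np.asarray(stack, dtype=np.float64), grid, warnings


_CENSOR_VALUES = {"none", "below_lloq", "above_uloq"}


def write_cytokine_csv(path: str | Path, table: pd.DataFrame) -> Path:
    """Write a cytokine table with the ``censor_flag`` on-disk column name."""
    path = Path(path)
    out = table.rename(columns={"censor": "censor_flag"})
    cols = [c for c in ("analyte", "condition", "replicate", "concentration_pg_ml", "censor_flag") if c in out.columns]
    out[cols].to_csv(path, index=False)
    return path


def read_cytokine_csv(path: str | Path) -> pd.DataFrame:
    """Read a cytokine CSV, validating schema row-wise with line numbers."""
    path = Path(path)
    table = pd.read_csv(path)
    table = table.rename(columns={"censor_flag": "censor"})
    required = {"analyte", "condition", "concentration_pg_ml"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if "censor" not in table.columns:
        table["censor"] = "none"
    if "replicate" not in table.columns:
        table["replicate"] = 1
    errors = []
    conc = pd.to_numeric(table["concentration_pg_ml"], errors="coerce")
    for i, row in enumerate(table.itertuples(index=False), start=2):  # header is line 1
        if np.isnan(conc.iloc[i - 2]) or conc.iloc[i - 2] < 0:
            errors.append(f"line {i}: bad concentration {row.concentration_pg_ml!r}")
        if row.censor not in _CENSOR_VALUES:
            errors.append(f"line {i}: bad censor flag {row.censor!r}")
    if errors:
        raise ValueError(f"{path}: schema violations:\n" + "\n".join(errors))
    table["concentration_pg_ml"] = conc
    return table
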