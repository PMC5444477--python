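"""Standard-format I/O: multi-page TIFF stacks with sidecar JSON metadata,
per-cell CSV tables, axis control points as JSON, meshes as PLY."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .core import CELL_CSV_COLUMNS, LabeledVolume
from .geometry import BezierAxis


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_stack(path, stack: np.ndarray, spacing=(1.0, 1.0, 1.0), **meta) -> None:
    """Write a 3D stack as multi-page TIFF (z pages) plus a sidecar JSON
    carrying voxel spacing and provenance metadata."""
    path = Path(path)
    arr = np.asarray(stack)
    if arr.ndim != 3:
        raise ValueError("stack must be 3D")
    tifffile.imwrite(path, arr)
    with open(_sidecar(path), "w") as fh:
        json.dump({"spacing_um_zyx": list(map(float, spacing)),
                   "dtype": str(arr.dtype), "shape": list(arr.shape), **meta}, fh, indent=2)


def read_stack(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read a stack and its spacing; spacing defaults to 1 µm if no sidecar."""
    path = Path(path)
    arr = tifffile.imread(path)
    spacing = (1.0, 1.0, 1.0)
    sc = _sidecar(path)
    if sc.exists():
        with open(sc) as fh:
            spacing = tuple(json.load(fh)["spacing_um_zyx"])
    return arr, spacing


def write_labels(path, volume: LabeledVolume, **meta) -> None:
    write_stack(path, volume.labels.astype(np.uint16 if volume.labels.max() < 2**16
                                           else np.int32),
                spacing=volume.spacing, kind="labels", **meta)


def read_labels(path) -> LabeledVolume:
    arr, spacing = read_stack(path)
    return LabeledVolume(arr.astype(np.int32), spacing)


def write_cells_csv(path, records: pd.DataFrame) -> None:
    """Write a per-cell table in the canonical column order."""
    missing = [c for c in CELL_CSV_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"records missing columns: {missing}")
    records[CELL_CSV_COLUMNS].to_csv(path, index=False)


def read_cells_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in CELL_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df


def write_axis_json(path, axis_points: np.ndarray) -> None:
    with open(path, "w") as fh:
        json.dump({"axis_points_um_zyx": np.asarray(axis_points, dtype=float).tolist()},
                  fh, indent=2)


def read_axis_json(path) -> np.ndarray:
    with open(path) as fh:
        return np.asarray(json.load(fh)["axis_points_um_zyx"], dtype=float)


def write_bezier_json(path, axis: BezierAxis) -> None:
    with open(path, "w") as fh:
        json.dump({"control_points_um_zyx": axis.control_points.tolist(),
                   "degree": axis.degree, "fit_rms_um": axis.fit_rms}, fh, indent=2)


def read_bezier_json(path) -> BezierAxis:
    with open(path) as fh:
        data = json.load(fh)
    axis = BezierAxis(np.asarray(data["control_points_um_zyx"], dtype=float))
    axis.fit_rms = data.get("fit_rms_um")
    return axis


def write_mesh_ply(path, mesh) -> None:
    """Export a CellMesh (or trimesh) as ASCII PLY."""
    tm = getattr(mesh, "trimesh", mesh)
    tm.export(Path(path), file_type="ply", encoding="ascii")
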