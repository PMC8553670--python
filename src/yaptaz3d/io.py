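"""Output writers: CSV time series, legacy-VTK snapshots, JSON metadata."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .geometry import CellGeometry
from .model_core import SpeciesState
from .solver import SimulationResult


def write_timeseries_csv(result: SimulationResult, path) -> None:
    """Long-format CSV: time, series, compartment, value, units."""
    result.to_frame().to_csv(path, index=False)


def write_summary_json(data: dict, path) -> None:
    Path(path).write_text(json.dumps(data, indent=2, default=_jsonable) + "\n")


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return str(obj)


def _cell_field_on_grid(geometry: CellGeometry, packed: np.ndarray) -> np.ndarray:
    """Scatter a packed cytosol array back onto the full grid (0 outside)."""
    full = np.zeros(geometry.grid_dims)
    full[geometry.cyt_index >= 0] = packed[geometry.cyt_index[geometry.cyt_index >= 0]]
    return full


def write_vtk(geometry: CellGeometry, path, fields: dict | None = None) -> None:
    """Legacy-ASCII VTK structured-points file with cell data.

    Always writes the cytosol and nucleus masks; ``fields`` may add packed
    cytosol arrays (e.g. species concentrations) as extra cell data.
    """
    nx, ny, nz = geometry.grid_dims
    dx, dy, dz = geometry.voxel_size
    ox, oy, oz = geometry.origin
    data = {
        "cytosol_mask": geometry.cytosol_mask.astype(float),
        "nucleus_mask": geometry.nucleus_mask.astype(float),
    }
    for name, arr in (fields or {}).items():
        data[name] = _cell_field_on_grid(geometry, np.asarray(arr))

    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("yaptaz3d voxelized cell\nASCII\nDATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {nx + 1} {ny + 1} {nz + 1}\n")
        fh.write(f"ORIGIN {ox} {oy} {oz}\n")
        fh.write(f"SPACING {dx} {dy} {dz}\n")
        fh.write(f"CELL_DATA {nx * ny * nz}\n")
        for name, arr in data.items():
            fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
            # VTK expects x varying fastest
            flat = np.transpose(arr, (2, 1, 0)).ravel()
            np.savetxt(fh, flat.reshape(-1, 1), fmt="%.6g")


def write_snapshot_vtk(geometry: CellGeometry, state: SpeciesState, path) -> None:
    """Snapshot of all volumetric species as VTK cell data."""
    write_vtk(geometry, path, fields=dict(state.vol))
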