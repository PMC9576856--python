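"""Lightweight writers: legacy-VTK meshes/surfaces, CSV traces, JSON.

The VTK writer emits ASCII legacy unstructured grids (hex8 + quad cells)
with part labels and fibre vectors as cell data — enough for ParaView
inspection without a heavyweight mesh-IO dependency.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

_VTK_HEX = 12
_VTK_QUAD = 9


def write_vtk(path, nodes, cells, cell_types=None, cell_data=None,
              point_data=None, title="tonosim"):
    """Write an ASCII legacy VTK unstructured grid.

    ``cells`` is a list of connectivity rows (hex8 or quad4);
    ``cell_data``/``point_data`` map names to scalar or vector arrays.
    """
    nodes = np.asarray(nodes, float)
    cells = [np.asarray(c, int) for c in cells]
    if cell_types is None:
        cell_types = [_VTK_HEX if len(c) == 8 else _VTK_QUAD for c in cells]
    lines = ["# vtk DataFile Version 3.0", title, "ASCII",
             "DATASET UNSTRUCTURED_GRID",
             f"POINTS {len(nodes)} double"]
    lines += [" ".join(f"{v:.9g}" for v in p) for p in nodes]
    total = sum(len(c) + 1 for c in cells)
    lines.append(f"CELLS {len(cells)} {total}")
    lines += [f"{len(c)} " + " ".join(map(str, c)) for c in cells]
    lines.append(f"CELL_TYPES {len(cells)}")
    lines += [str(t) for t in cell_types]

    def emit(block, n, data):
        out = [f"{block}_DATA {n}"]
        for name, arr in (data or {}).items():
            arr = np.asarray(arr, float)
            if arr.ndim == 1:
                out.append(f"SCALARS {name} double 1")
                out.append("LOOKUP_TABLE default")
                out += [f"{v:.9g}" for v in arr]
            else:
                out.append(f"VECTORS {name} double")
                out += [" ".join(f"{v:.9g}" for v in row) for row in arr]
        return out

    if cell_data:
        lines += emit("CELL", len(cells), cell_data)
    if point_data:
        lines += emit("POINT", len(nodes), point_data)
    Path(path).write_text("\n".join(lines) + "\n")


def write_mesh_vtk(path, mesh, displacements=None):
    """Export an :class:`EyeMesh` with part labels and fibre frames."""
    nodes = mesh.nodes if displacements is None \
        else mesh.nodes + displacements
    cells = [list(h) for h in mesh.hexes] + [list(s) for s in mesh.shells]
    part = np.concatenate([mesh.hex_part,
                           mesh.shell_part]).astype(float)
    fib_m = np.vstack([np.nan_to_num(mesh.fiber_m),
                       np.zeros((len(mesh.shells), 3))])
    fib_n = np.vstack([np.nan_to_num(mesh.fiber_n),
                       np.zeros((len(mesh.shells), 3))])
    write_vtk(path, nodes, cells,
              cell_data={"part": part, "fiber_m": fib_m, "fiber_n": fib_n})


def mesh_summary_frame(mesh):
    """Part-wise element counts and volumes as a DataFrame."""
    from .fem_engine import hex_volumes
    vols = hex_volumes(mesh.nodes, mesh.hexes)
    rows = []
    for i, name in enumerate(mesh.part_names):
        sel = mesh.hex_part == i
        nsh = int((mesh.shell_part == i).sum())
        if not sel.any() and not nsh:
            continue
        rows.append({"part": name, "hexes": int(sel.sum()),
                     "shells": nsh,
                     "volume_mm3": float(vols[sel].sum())})
    return pd.DataFrame(rows)


def write_traces_csv(path, history):
    """Time traces (IOP per cavity, apex pressure, jet velocity) as CSV."""
    data = {"time_ms": history.times,
            "apex_displacement_mm": history.apex_axial}
    for name, tr in history.cavity_pressure.items():
        data[f"iop_{name}_mmHg"] = tr
    if history.apex_air_pressure is not None:
        data["apex_air_pressure_mmHg"] = history.apex_air_pressure
    if history.jet_velocity is not None:
        data["jet_velocity_mm_per_ms"] = history.jet_velocity
    pd.DataFrame(data).to_csv(path, index=False)


def write_report_json(path, report_or_dict):
    d = report_or_dict if isinstance(report_or_dict, dict) \
        else report_or_dict.to_dict()
    Path(path).write_text(json.dumps(_jsonable(d), indent=2) + "\n")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
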