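"""Plain-text writers: legacy-ASCII VTK, CSV tables, polygon lists.

All floating-point output uses a fixed ``%.9g`` format so that identical
runs produce byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .chemistry import ChemState, PatchSummary
from .geometry import CellDomain2D, ShellMesh

_F = "%.9g"


def _fmt(vals) -> str:
    return " ".join(_F % v for v in np.atleast_1d(vals))


def write_cell_domain_vtk(domain: CellDomain2D, path, state: ChemState | None = None):
    """Compartment tessellation as VTK polygons, with optional A/R_a/R_i
    cell fields."""
    path = Path(path)
    verts, polys = [], []
    for c in domain.compartments:
        start = len(verts)
        verts.extend([(x, y, 0.0) for x, y in c.polygon])
        polys.append(list(range(start, start + len(c.polygon))))
    lines = ["# vtk DataFile Version 3.0", "rootpatch cell domain", "ASCII",
             "DATASET UNSTRUCTURED_GRID", f"POINTS {len(verts)} double"]
    lines += [_fmt(v) for v in verts]
    ncell = len(polys)
    size = sum(len(p) + 1 for p in polys)
    lines.append(f"CELLS {ncell} {size}")
    lines += [f"{len(p)} " + " ".join(map(str, p)) for p in polys]
    lines.append(f"CELL_TYPES {ncell}")
    lines += ["7"] * ncell                       # VTK_POLYGON
    if state is not None:
        lines.append(f"CELL_DATA {ncell}")
        for name, arr in (("A", state.A), ("R_a", state.R_a), ("R_i", state.R_i)):
            lines += [f"SCALARS {name} double 1", "LOOKUP_TABLE default"]
            lines += [_F % v for v in arr]
    path.write_text("\n".join(lines) + "\n")


def write_polygon_list(domain: CellDomain2D, path):
    """One compartment per line: id followed by x y vertex pairs."""
    with open(path, "w") as fh:
        for c in domain.compartments:
            coords = " ".join(_F % v for xy in c.polygon for v in xy)
            fh.write(f"{c.id} {coords}\n")


def write_shell_mesh_vtk(mesh: ShellMesh, path, displacements=None,
                         stress_field=None):
    """Wall-patch mesh as VTK quads/triangles with optional point
    displacements and per-element stress data."""
    path = Path(path)
    lines = ["# vtk DataFile Version 3.0", "rootpatch wall mesh", "ASCII",
             "DATASET UNSTRUCTURED_GRID", f"POINTS {len(mesh.nodes)} double"]
    lines += [_fmt(p) for p in mesh.nodes]
    ncell = mesh.n_elements
    size = sum(len(mesh.element_nodes(e)) + 1 for e in range(ncell))
    lines.append(f"CELLS {ncell} {size}")
    for e in range(ncell):
        conn = mesh.element_nodes(e)
        lines.append(f"{len(conn)} " + " ".join(map(str, conn)))
    lines.append(f"CELL_TYPES {ncell}")
    lines += ["9" if len(mesh.element_nodes(e)) == 4 else "5"
              for e in range(ncell)]         # VTK_QUAD / VTK_TRIANGLE
    if displacements is not None:
        lines += [f"POINT_DATA {len(mesh.nodes)}",
                  "VECTORS displacement double"]
        lines += [_fmt(u) for u in displacements]
    cell_blocks = []
    if stress_field is not None:
        cell_blocks += [
            ("SCALARS sigma_1 double 1\nLOOKUP_TABLE default",
             [_F % v for v in stress_field.sigma_1]),
            ("SCALARS sigma_2 double 1\nLOOKUP_TABLE default",
             [_F % v for v in stress_field.sigma_2]),
            ("VECTORS dir_1 double", [_fmt(v) for v in stress_field.dir_1]),
            ("VECTORS dir_2 double", [_fmt(v) for v in stress_field.dir_2]),
            ("TENSORS sigma double",
             [_fmt(s.ravel()) for s in stress_field.sigma]),
        ]
    if cell_blocks:
        lines.append(f"CELL_DATA {ncell}")
        for header, rows in cell_blocks:
            lines.append(header)
            lines += rows
    path.write_text("\n".join(lines) + "\n")


def write_compartment_csv(domain: CellDomain2D, state: ChemState, path):
    cents = domain.centroids
    df = pd.DataFrame({
        "id": [c.id for c in domain.compartments],
        "x": cents[:, 0], "y": cents[:, 1], "area": domain.areas,
        "A": state.A, "R_a": state.R_a, "R_i": state.R_i,
    })
    df.to_csv(path, index=False, float_format=_F)


def write_patch_summary_json(summary: PatchSummary, path, extra: dict | None = None):
    payload = {
        "n_peaks": summary.n_peaks,
        "peaks": [{"centroid": [float(x), float(y)],
                   "max_concentration": m, "total_active_rop": t}
                  for (x, y), m, t in summary.peaks],
        "basal_offset": None if np.isnan(summary.basal_offset)
        else float(summary.basal_offset),
        "lateral_offset": None if np.isnan(summary.lateral_offset)
        else float(summary.lateral_offset),
    }
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def write_stress_csv(stress_field, path):
    df = pd.DataFrame({
        "element": np.arange(len(stress_field.sigma_1)),
        "x": stress_field.centroids[:, 0],
        "y": stress_field.centroids[:, 1],
        "sigma_1": stress_field.sigma_1,
        "sigma_2": stress_field.sigma_2,
        "dir1_x": stress_field.dir_1[:, 0],
        "dir1_y": stress_field.dir_1[:, 1],
        "dir1_z": stress_field.dir_1[:, 2],
    })
    df.to_csv(path, index=False, float_format=_F)


def read_polygon_list(path) -> list[tuple[int, np.ndarray]]:
    out = []
    for line in Path(path).read_text().splitlines():
        parts = line.split()
        if not parts:
            continue
        cid = int(parts[0])
        xy = np.array(parts[1:], dtype=float).reshape(-1, 2)
        out.append((cid, xy))
    return out
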