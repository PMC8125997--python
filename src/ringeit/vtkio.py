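"""Minimal legacy-VTK (ASCII) export for triangle meshes.

Writes the classic ``# vtk DataFile Version 2.0`` unstructured-grid
format with optional per-cell and per-point scalar fields, enough for
ParaView/VisIt inspection of meshes, phantoms and reconstructions.
"""

from __future__ import annotations

import numpy as np

__all__ = ["write_vtk"]


def write_vtk(path, node_coords, triangles, cell_data=None, point_data=None, title="ringeit mesh"):
    nodes = np.asarray(node_coords, dtype=float)
    tris = np.asarray(triangles, dtype=np.int64)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 2.0\n")
        fh.write(f"{title}\n")
        fh.write("ASCII\nDATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {len(nodes)} double\n")
        for x, y in nodes:
            fh.write(f"{x:.12g} {y:.12g} 0\n")
        fh.write(f"CELLS {len(tris)} {4 * len(tris)}\n")
        for a, b, c in tris:
            fh.write(f"3 {a} {b} {c}\n")
        fh.write(f"CELL_TYPES {len(tris)}\n")
        fh.write("5\n" * len(tris))  # VTK_TRIANGLE
        if cell_data:
            fh.write(f"CELL_DATA {len(tris)}\n")
            for name, vals in cell_data.items():
                fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                for v in np.asarray(vals, dtype=float):
                    fh.write(f"{v:.12g}\n")
        if point_data:
            fh.write(f"POINT_DATA {len(nodes)}\n")
            for name, vals in point_data.items():
                fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                for v in np.asarray(vals, dtype=float):
                    fh.write(f"{v:.12g}\n")
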