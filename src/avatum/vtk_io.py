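"""Legacy-VTK ASCII export of chip fields (rectilinear grid).

The legacy RECTILINEAR_GRID format is plain text and readable by
ParaView/VisIt; fields are written as CELL_DATA: cell type, pressure,
cell-centred velocity, nutrient concentrations and zone labels. Only
the meshed symmetry half is written.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

__all__ = ["write_vtk"]


def _write_array(fh, name, arr, vectors=False):
    flat = np.asarray(arr)
    if vectors:
        fh.write(f"VECTORS {name} float\n")
        data = flat.reshape(-1, 3, order="F")
        np.savetxt(fh, data, fmt="%.6e")
    else:
        fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
        np.savetxt(fh, flat.ravel(order="F")[:, None], fmt="%.6e")


def write_vtk(path, domain, flow=None, conc=None) -> Path:
    """Write domain (and optional flow/concentration fields) to ``path``."""
    path = Path(path)
    nx, ny, nz = domain.shape
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("avatum chip snapshot\nASCII\nDATASET RECTILINEAR_GRID\n")
        fh.write(f"DIMENSIONS {nx + 1} {ny + 1} {nz + 1}\n")
        for tag, edges in (
            ("X_COORDINATES", domain.x_edges),
            ("Y_COORDINATES", domain.y_edges),
            ("Z_COORDINATES", domain.z_edges),
        ):
            fh.write(f"{tag} {len(edges)} float\n")
            fh.write(" ".join(f"{v:.6e}" for v in edges) + "\n")
        fh.write(f"CELL_DATA {nx * ny * nz}\n")
        _write_array(fh, "cell_type", domain.cell_type.astype(float))
        if flow is not None:
            _write_array(fh, "pressure", np.nan_to_num(flow.p))
            _write_array(fh, "velocity", flow.cell_velocity(), vectors=True)
        if conc is not None:
            _write_array(fh, "c_glucose", np.nan_to_num(conc.c_glucose))
            _write_array(fh, "c_oxygen", np.nan_to_num(conc.c_oxygen))
            _write_array(fh, "zone_label", conc.labels.astype(float))
    return path
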