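"""Legacy-ASCII VTK structured-points export for visualisation.

Writes voltage fields, activation maps and per-direction conductance
magnitudes as STRUCTURED_POINTS datasets readable by ParaView/VisIt.
The legacy text format is written directly (it is a trivial header plus
one value per line); values on non-tissue nodes are written as the fill
value (default -9999).
"""

from __future__ import annotations

import numpy as np

from .grid import StructuredGrid

__all__ = ["write_vtk_structured_points"]

_FILL = -9999.0


def write_vtk_structured_points(path, grid: StructuredGrid, fields: dict,
                                fill: float = _FILL) -> None:
    """Write scalar fields to a legacy VTK structured-points file.

    ``fields`` maps field names to arrays that are either full-grid
    (shape ``grid.dims`` or length ``n_nodes`` in linear order) or
    tissue-local (length ``n_tissue``); tissue-local data are scattered
    onto the grid with ``fill`` elsewhere.  NaNs are replaced by ``fill``
    (VTK readers choke on NaN in ASCII files).
    """
    if not fields:
        raise ValueError("no fields to write")
    nd = grid.ndim
    dims = grid.dims + (1,) * (3 - nd)
    spacing = grid.spacing + (1.0,) * (3 - nd)
    n = int(np.prod(dims))

    def linearise(arr):
        a = np.asarray(arr, dtype=float)
        if a.shape == grid.dims:
            a = a.ravel(order="F")
        elif a.shape == (grid.n_nodes,):
            pass
        elif a.shape == (grid.n_tissue,):
            full = np.full(grid.n_nodes, fill)
            full[grid.tissue_linear] = a
            a = full
        else:
            raise ValueError(
                f"field shape {a.shape} matches neither grid dims "
                f"{grid.dims}, n_nodes nor n_tissue")
        return np.where(np.isfinite(a), a, fill)

    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("cardionet structured points export\n")
        fh.write("ASCII\n")
        fh.write("DATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {dims[0]} {dims[1]} {dims[2]}\n")
        fh.write("ORIGIN 0 0 0\n")
        fh.write(f"SPACING {spacing[0]:g} {spacing[1]:g} {spacing[2]:g}\n")
        fh.write(f"POINT_DATA {n}\n")
        for name, arr in fields.items():
            data = linearise(arr)
            safe = name.replace(" ", "_")
            fh.write(f"SCALARS {safe} float 1\n")
            fh.write("LOOKUP_TABLE default\n")
            fh.write("\n".join(f"{v:.6g}" for v in data))
            fh.write("\n")
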