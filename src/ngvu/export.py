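"""Text exports: tidy CSV time series and legacy ASCII VTK fields.

Legacy VTK is written directly (STRUCTURED_POINTS for tissue fields,
POLYDATA lines for the capillary network) so results open in standard mesh
viewers without binary dependencies.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def write_timeseries_csv(columns: dict, path) -> None:
    pd.DataFrame(columns).to_csv(path, index=False)


def read_timeseries_csv(path) -> dict:
    df = pd.read_csv(path)
    return {c: df[c].to_numpy() for c in df.columns}


def write_vtk_structured(field: np.ndarray, spacing, path,
                         name: str = "field") -> None:
    """Cell-centered scalar field on a uniform grid -> STRUCTURED_POINTS."""
    field = np.asarray(field)
    nx, ny, nz = field.shape
    sx, sy, sz = spacing
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(f"{name}\nASCII\nDATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {nx} {ny} {nz}\n")
        fh.write(f"ORIGIN {sx / 2:g} {sy / 2:g} {sz / 2:g}\n")
        fh.write(f"SPACING {sx:g} {sy:g} {sz:g}\n")
        fh.write(f"POINT_DATA {nx * ny * nz}\n")
        fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
        # VTK expects x fastest; our arrays are (x, y, z) C-ordered
        flat = np.transpose(field, (2, 1, 0)).ravel()
        for chunk in np.array_split(flat, max(1, flat.size // 9)):
            fh.write(" ".join(f"{v:.6g}" for v in chunk) + "\n")


def write_vtk_polylines(nodes: np.ndarray, segments: np.ndarray,
                        cell_values: dict, path,
                        title: str = "network") -> None:
    """1D network as POLYDATA lines with per-segment CELL_DATA scalars."""
    nodes = np.asarray(nodes)
    segments = np.asarray(segments, dtype=int)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(f"{title}\nASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {len(nodes)} float\n")
        for x, y, z in nodes:
            fh.write(f"{x:.6g} {y:.6g} {z:.6g}\n")
        fh.write(f"LINES {len(segments)} {3 * len(segments)}\n")
        for a, b in segments:
            fh.write(f"2 {a} {b}\n")
        if cell_values:
            fh.write(f"CELL_DATA {len(segments)}\n")
            for name, vals in cell_values.items():
                fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
                fh.write("\n".join(f"{v:.6g}" for v in np.asarray(vals)))
                fh.write("\n")


def read_vtk_structured(path):
    """Minimal reader for round-trip checks of our own writer."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    dims = spacing = None
    data_start = None
    for i, ln in enumerate(lines):
        if ln.startswith("DIMENSIONS"):
            dims = tuple(int(v) for v in ln.split()[1:])
        elif ln.startswith("SPACING"):
            spacing = tuple(float(v) for v in ln.split()[1:])
        elif ln.startswith("LOOKUP_TABLE"):
            data_start = i + 1
            break
    vals = np.array([float(v) for ln in lines[data_start:]
                     for v in ln.split()])
    nx, ny, nz = dims
    field = vals.reshape(nz, ny, nx).transpose(2, 1, 0)
    return field, spacing
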