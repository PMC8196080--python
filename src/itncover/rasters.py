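"""Gridded-surface I/O on a planar row-major grid.

Rasters are exchanged as ESRI ASCII grids (``.asc``), a plain-text
georeferenced format readable by every GIS stack. The abstract grid stands in
for the 5-by-5-km analysis pixels: pixel (0, 0) is the north-west corner,
rows increase southwards, columns eastwards, and distances are measured in
grid cell units.
"""

from __future__ import annotations

import numpy as np

NODATA = -9999.0


def write_ascii_grid(path, array: np.ndarray, cellsize: float = 1.0,
                     xllcorner: float = 0.0, yllcorner: float = 0.0) -> None:
    """Write a 2-D array (NaN -> NODATA) as an ESRI ASCII grid."""
    a = np.asarray(array, dtype=float)
    if a.ndim != 2:
        raise ValueError("raster must be 2-D")
    filled = np.where(np.isnan(a), NODATA, a)
    header = (
        f"ncols {a.shape[1]}\n"
        f"nrows {a.shape[0]}\n"
        f"xllcorner {xllcorner}\n"
        f"yllcorner {yllcorner}\n"
        f"cellsize {cellsize}\n"
        f"NODATA_value {NODATA}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, filled, fmt="%.6g")


def read_ascii_grid(path) -> tuple[np.ndarray, dict]:
    """Read an ESRI ASCII grid; NODATA cells come back as NaN.

    Returns (array, header_dict).
    """
    header = {}
    with open(path) as fh:
        lines = fh.readlines()
    n_header = 0
    for line in lines:
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"
        }:
            header[parts[0].lower()] = float(parts[1])
            n_header += 1
        else:
            break
    arr = np.loadtxt(lines[n_header:], dtype=float)
    arr = np.atleast_2d(arr)
    nodata = header.get("nodata_value", NODATA)
    arr = np.where(arr == nodata, np.nan, arr)
    return arr, header


def grid_coords(shape: tuple[int, int]) -> np.ndarray:
    """(n_cells, 2) array of (row, col) centre coordinates, row-major order."""
    rows, cols = np.indices(shape)
    return np.column_stack([rows.ravel(), cols.ravel()]).astype(float)
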