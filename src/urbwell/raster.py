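"""Georeferenced single-band raster grid.

A minimal container for intensity surfaces (nighttime light, NDVI, air
temperature, ...) on a regular projected grid.  Row 0 is the top of the
map; a point (x, y) falls in cell (row, col) via half-open intervals
``[x0 + col*dx, x0 + (col+1)*dx)``.  Rasters are read and written as
ESRI ASCII grids (AAIGrid), a plain-text format every GIS stack accepts.

Areas are computed from ``cell_size`` assuming an equal-area projection;
geographic (lon/lat) inputs must be projected first, otherwise areas are
meaningless and the package will not notice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

NODATA_DEFAULT = -1.0


@dataclass
class RasterGrid:
    """A rows x cols nonnegative intensity field with a map origin.

    Parameters
    ----------
    values : ndarray
        2-D float array.  Cells equal to ``nodata`` are missing.
    origin : tuple of float
        (x0, y0) map coordinates of the *lower-left* corner of the grid.
    cell_size : float
        Edge length of a square cell in map units (> 0).
    nodata : float
        Missing-value marker, default -1.
    """

    values: np.ndarray
    origin: tuple[float, float] = (0.0, 0.0)
    cell_size: float = 1.0
    nodata: float = NODATA_DEFAULT

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        finite = self.values[self.values != self.nodata]
        if finite.size and not np.all(np.isfinite(finite)):
            raise ValueError("raster contains non-finite data values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def valid_mask(self) -> np.ndarray:
        """Boolean grid of cells carrying data."""
        return self.values != self.nodata

    def cell_area(self) -> float:
        """Area of one cell in map-unit squared (km^2 if units are km)."""
        return self.cell_size ** 2

    def point_to_cell(self, x: float, y: float) -> tuple[int, int]:
        """Map coordinates to (row, col); row 0 is the top row."""
        nrows = self.values.shape[0]
        col = int(np.floor((x - self.origin[0]) / self.cell_size))
        row_from_bottom = int(np.floor((y - self.origin[1]) / self.cell_size))
        return nrows - 1 - row_from_bottom, col

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        nrows = self.values.shape[0]
        x = self.origin[0] + (col + 0.5) * self.cell_size
        y = self.origin[1] + (nrows - 1 - row + 0.5) * self.cell_size
        return x, y

    def contains(self, x: float, y: float) -> bool:
        r, c = self.point_to_cell(x, y)
        nr, nc = self.values.shape
        return 0 <= r < nr and 0 <= c < nc


def write_ascii_grid(raster: RasterGrid, path: str | Path) -> None:
    """Write an ESRI ASCII grid (.asc)."""
    nrows, ncols = raster.shape
    header = (
        f"ncols {ncols}\n"
        f"nrows {nrows}\n"
        f"xllcorner {raster.origin[0]:.6f}\n"
        f"yllcorner {raster.origin[1]:.6f}\n"
        f"cellsize {raster.cell_size:.6f}\n"
        f"NODATA_value {raster.nodata:g}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, raster.values, fmt="%.6g")


def read_ascii_grid(path: str | Path) -> RasterGrid:
    """Read an ESRI ASCII grid (.asc)."""
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            key, _, val = line.partition(" ")
            key = key.strip().lower()
            if key in {"ncols", "nrows", "xllcorner", "yllcorner",
                       "cellsize", "nodata_value"}:
                header[key] = float(val)
                pos = fh.tell()
            else:  # optional NODATA line absent
                break
        fh.seek(pos)
        values = np.loadtxt(fh, ndmin=2)
    nodata = header.get("nodata_value", NODATA_DEFAULT)
    grid = RasterGrid(
        values=values,
        origin=(header["xllcorner"], header["yllcorner"]),
        cell_size=header["cellsize"],
        nodata=nodata,
    )
    if grid.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(f"header/body shape mismatch in {path}")
    return grid
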