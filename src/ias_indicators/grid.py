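"""Geographic grid geometry shared by rasters, climate stacks and masks.

All gridded data in this package live on north-up, axis-aligned WGS84
longitude/latitude grids. The affine geotransform is therefore fully
described by four numbers: the west edge, the north edge, and the cell
sizes in degrees. Rows advance southwards, columns eastwards, matching the
GeoTIFF convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GridTransform"]


@dataclass(frozen=True)
class GridTransform:
    """North-up affine transform of a lon/lat grid.

    Parameters
    ----------
    west, north
        Outer edge of the top-left cell, in decimal degrees.
    xres, yres
        Cell width and height in degrees; both positive.
    """

    west: float
    north: float
    xres: float
    yres: float

    def __post_init__(self) -> None:
        if self.xres <= 0 or self.yres <= 0:
            raise ValueError("cell sizes must be positive")

    def rowcol(self, lon, lat):
        """Map coordinates to (row, col) indices (floor; edges belong to the
        cell to the south-east, except nothing is clipped — callers check
        bounds)."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.west) / self.xres).astype(int)
        row = np.floor((self.north - lat) / self.yres).astype(int)
        return row, col

    def cell_centers(self, shape: tuple[int, int]):
        """Return (lons, lats) 1-D center coordinate arrays for a grid of
        ``shape`` (nrows, ncols)."""
        nrows, ncols = shape
        lons = self.west + (np.arange(ncols) + 0.5) * self.xres
        lats = self.north - (np.arange(nrows) + 0.5) * self.yres
        return lons, lats

    def bounds(self, shape: tuple[int, int]) -> tuple[float, float, float, float]:
        """(west, south, east, north) outer bounds for a grid of ``shape``."""
        nrows, ncols = shape
        return (
            self.west,
            self.north - nrows * self.yres,
            self.west + ncols * self.xres,
            self.north,
        )

    def approx_equal(self, other: "GridTransform", tol: float = 1e-9) -> bool:
        return (
            abs(self.west - other.west) <= tol
            and abs(self.north - other.north) <= tol
            and abs(self.xres - other.xres) <= tol
            and abs(self.yres - other.yres) <= tol
        )
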