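"""Georeferenced raster grids.

A :class:`RasterGrid` is a rectangular grid of cell values in a projected
coordinate system (metres).  Grids are cell-centre registered: ``origin`` is
the centre of the lower-left cell, row 0 of ``values`` is the northernmost
row.  ``nodata`` cells are carried as NaN internally and never participate in
statistics.

Grids serialise to the plain-text ESRI ASCII grid format (``.asc``), which
round-trips values exactly at the printed precision and needs no binary
dependencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["RasterGrid", "read_ascii_grid", "write_ascii_grid"]

_NODATA_OUT = -9999.0


@dataclass
class RasterGrid:
    """A single-band raster: 2-D float values plus georeferencing.

    Parameters
    ----------
    values : ndarray, shape (nrows, ncols)
        Cell values; NaN marks nodata. Row 0 is the northern edge.
    origin : (float, float)
        (x, y) of the centre of the lower-left cell, in projected metres.
    cell_size : float
        Cell edge length in metres; must be positive.
    """

    values: np.ndarray
    origin: tuple[float, float]
    cell_size: float = 30.0
    name: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if self.cell_size <= 0:
            raise ValueError(f"cell_size must be positive, got {self.cell_size}")
        self.origin = (float(self.origin[0]), float(self.origin[1]))

    # -- geometry -----------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid's outer cell edges."""
        x0, y0 = self.origin
        h = self.cell_size / 2.0
        return (
            x0 - h,
            y0 - h,
            x0 + (self.ncols - 1) * self.cell_size + h,
            y0 + (self.nrows - 1) * self.cell_size + h,
        )

    def same_geometry(self, other: "RasterGrid", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and abs(self.cell_size - other.cell_size) <= tol
            and abs(self.origin[0] - other.origin[0]) <= tol
            and abs(self.origin[1] - other.origin[1]) <= tol
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Arrays (X, Y) of cell-centre coordinates, each shaped like values."""
        x0, y0 = self.origin
        xs = x0 + np.arange(self.ncols) * self.cell_size
        ys = y0 + (self.nrows - 1 - np.arange(self.nrows)) * self.cell_size
        return np.meshgrid(xs, ys)

    def index_of(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """(row, col) of the cell containing each point; no bounds clipping."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        x0, y0 = self.origin
        h = self.cell_size / 2.0
        col = np.floor((x - (x0 - h)) / self.cell_size).astype(int)
        row = self.nrows - 1 - np.floor((y - (y0 - h)) / self.cell_size).astype(int)
        return row, col

    def sample(self, x, y) -> np.ndarray:
        """Value of the cell containing each point (NaN outside the grid)."""
        row, col = self.index_of(x, y)
        row = np.atleast_1d(row)
        col = np.atleast_1d(col)
        out = np.full(row.shape, np.nan)
        ok = (row >= 0) & (row < self.nrows) & (col >= 0) & (col < self.ncols)
        out[ok] = self.values[row[ok], col[ok]]
        return out

    def with_values(self, values: np.ndarray, name: str | None = None) -> "RasterGrid":
        """A new grid sharing this grid's georeferencing."""
        return RasterGrid(
            values=np.asarray(values, dtype=float),
            origin=self.origin,
            cell_size=self.cell_size,
            name=self.name if name is None else name,
        )

    @property
    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.values)


def write_ascii_grid(grid: RasterGrid, path: str | Path) -> None:
    """Write an ESRI ASCII grid (.asc); NaN cells become the nodata marker."""
    vals = np.where(np.isfinite(grid.values), grid.values, _NODATA_OUT)
    header = (
        f"ncols {grid.ncols}\n"
        f"nrows {grid.nrows}\n"
        f"xllcenter {grid.origin[0]:.6f}\n"
        f"yllcenter {grid.origin[1]:.6f}\n"
        f"cellsize {grid.cell_size:.6f}\n"
        f"NODATA_value {_NODATA_OUT}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt="%.8g")


def read_ascii_grid(path: str | Path, name: str = "") -> RasterGrid:
    """Read an ESRI ASCII grid written by :func:`write_ascii_grid`."""
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        vals = np.loadtxt(fh)
    vals = np.atleast_2d(vals)
    nodata = header.get("nodata_value", _NODATA_OUT)
    vals = np.where(vals == nodata, np.nan, vals)
    if "xllcenter" in header:
        origin = (header["xllcenter"], header["yllcenter"])
    else:  # corner-registered file: shift to centres
        half = header["cellsize"] / 2.0
        origin = (header["xllcorner"] + half, header["yllcorner"] + half)
    return RasterGrid(vals, origin=origin, cell_size=header["cellsize"], name=name)
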