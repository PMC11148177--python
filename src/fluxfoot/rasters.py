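"""Tower-centred metric grids and raster containers.

All spatial data in this package live on square grids centred on the flux
tower: x grows eastward, y grows northward, and the tower sits at the grid
origin (0, 0).  Row 0 is the northernmost row so arrays print the way maps
are drawn.  Rasters are written as headered ESRI ASCII grids, which keeps
every artefact plain text.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "GridSpec",
    "CategoricalRaster",
    "ContinuousRaster",
    "write_ascii_grid",
    "read_ascii_grid",
]


@dataclass(frozen=True)
class GridSpec:
    """Square tower-centred grid: cells of ``cell_size`` m spanning ±``half_width`` m."""

    cell_size: float
    half_width: float

    def __post_init__(self) -> None:
        if self.cell_size <= 0 or self.half_width <= 0:
            raise ValueError("cell_size and half_width must be positive")
        ratio = 2.0 * self.half_width / self.cell_size
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError(
                f"cell size {self.cell_size} m does not divide the "
                f"{2 * self.half_width} m extent"
            )

    @property
    def n(self) -> int:
        """Number of cells per side."""
        return int(round(2.0 * self.half_width / self.cell_size))

    @property
    def x_centers(self) -> np.ndarray:
        c = self.cell_size
        return -self.half_width + c / 2.0 + c * np.arange(self.n)

    @property
    def y_centers(self) -> np.ndarray:
        c = self.cell_size
        return self.half_width - c / 2.0 - c * np.arange(self.n)

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) cell-centre coordinates, shape (n, n)."""
        return np.meshgrid(self.x_centers, self.y_centers)

    def index_of(self, x, y):
        """Row/col of the cell containing metric point(s) (x, y); -1 outside."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x + self.half_width) / self.cell_size).astype(int)
        row = np.floor((self.half_width - y) / self.cell_size).astype(int)
        bad = (col < 0) | (col >= self.n) | (row < 0) | (row >= self.n)
        col = np.where(bad, -1, col)
        row = np.where(bad, -1, row)
        return row, col


@dataclass
class CategoricalRaster:
    """Integer-coded raster (e.g. land-cover classes) on a tower-centred grid."""

    grid: GridSpec
    codes: np.ndarray
    nodata: int = -1

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int32)
        if self.codes.shape != (self.grid.n, self.grid.n):
            raise ValueError("codes shape does not match grid")

    def sample(self, x, y):
        """Nearest-neighbour class code at metric point(s); nodata outside."""
        row, col = self.grid.index_of(x, y)
        out = np.full(np.shape(row), self.nodata, dtype=np.int32)
        ok = row >= 0
        out[ok] = self.codes[row[ok], col[ok]]
        return out


@dataclass
class ContinuousRaster:
    """Float raster (NDVI, reflectance bands); NaN marks nodata."""

    grid: GridSpec
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.n, self.grid.n):
            raise ValueError("values shape does not match grid")

    @property
    def mask(self) -> np.ndarray:
        """True where data are valid."""
        return np.isfinite(self.values)

    def sample(self, x, y):
        """Nearest-neighbour value at metric point(s); NaN outside."""
        row, col = self.grid.index_of(x, y)
        out = np.full(np.shape(row), np.nan, dtype=float)
        ok = row >= 0
        out[ok] = self.values[row[ok], col[ok]]
        return out


_NODATA_CONT = -9999.0


def write_ascii_grid(path: str | Path, raster: CategoricalRaster | ContinuousRaster) -> None:
    """Write a raster as a headered ESRI ASCII grid (plain text)."""
    g = raster.grid
    path = Path(path)
    if isinstance(raster, CategoricalRaster):
        nodata = raster.nodata
        body = raster.codes
        fmt = "%d"
    else:
        nodata = _NODATA_CONT
        body = np.where(raster.mask, raster.values, nodata)
        fmt = "%.6g"
    header = (
        f"ncols {g.n}\n"
        f"nrows {g.n}\n"
        f"xllcorner {-g.half_width:.6f}\n"
        f"yllcorner {-g.half_width:.6f}\n"
        f"cellsize {g.cell_size:.6f}\n"
        f"NODATA_value {nodata}\n"
    )
    with path.open("w") as fh:
        fh.write(header)
        np.savetxt(fh, body, fmt=fmt)


def read_ascii_grid(path: str | Path, categorical: bool = False):
    """Read a headered ESRI ASCII grid written by :func:`write_ascii_grid`."""
    path = Path(path)
    header: dict[str, float] = {}
    with path.open() as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        body = np.loadtxt(fh)
    cell = header["cellsize"]
    n = int(header["ncols"])
    grid = GridSpec(cell_size=cell, half_width=n * cell / 2.0)
    body = np.atleast_2d(body)
    if categorical:
        return CategoricalRaster(grid, body.astype(np.int32), nodata=int(header["nodata_value"]))
    vals = body.astype(float)
    vals[vals == header["nodata_value"]] = np.nan
    return ContinuousRaster(grid, vals)
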