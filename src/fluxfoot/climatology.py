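"""Cumulative footprint climatology and percentile source-area contours.

Half-hourly footprints are accumulated cell-wise and renormalized to a
probability surface (the annual cumulative footprint climatology, ACFC).
Percentile source areas (50/60/70/80 %) are defined on cells: the smallest
set of highest-weight cells whose summed weight reaches the level.  The
polyline boundary is traced by marching squares and is cosmetic; the cell
mask is authoritative for areas and overlays.  Fetch is the maximum
distance from the tower to an 80 %-boundary cell centre, and the symmetry
index SI = A / (π · fetch²) measures the compactness of the 80 % contour
(1 for a tower-centred disc).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from scipy import ndimage
from skimage import measure

from .footprint import FootprintGrid
from .rasters import GridSpec

log = logging.getLogger(__name__)

__all__ = [
    "ACFC",
    "ContourLevel",
    "ContourSet",
    "accumulate",
    "extract_contours",
    "symmetry_index",
]

DEFAULT_LEVELS = (50, 60, 70, 80)


@dataclass
class ACFC:
    """Normalized cumulative footprint climatology (cell weights sum to 1)."""

    grid: GridSpec
    weights: np.ndarray
    n_contributing: int

    def resample_weights(self, target: GridSpec) -> np.ndarray:
        """Climatology weight of the source cell under each target cell centre."""
        X, Y = target.meshgrid()
        row, col = self.grid.index_of(X, Y)
        out = np.zeros_like(X)
        ok = row >= 0
        out[ok] = self.weights[row[ok], col[ok]]
        return out


@dataclass
class ContourLevel:
    level: int
    mask: np.ndarray
    area_m2: float
    polylines: list[np.ndarray] = field(default_factory=list)  # (k, 2) x,y metres


@dataclass
class ContourSet:
    grid: GridSpec
    levels: dict[int, ContourLevel]
    fetch_m: float
    si: float

    def mask(self, level: int = 80) -> np.ndarray:
        return self.levels[level].mask

    def area(self, level: int = 80) -> float:
        return self.levels[level].area_m2


def accumulate(footprints: Iterable[FootprintGrid]) -> ACFC:
    """Cell-wise sum of footprints renormalized to total weight 1."""
    total = None
    grid = None
    n = 0
    for fp in footprints:
        if grid is None:
            grid = fp.grid
            total = np.zeros_like(fp.weights)
        elif fp.grid != grid:
            raise ValueError("footprints accumulated on mismatched grids")
        total += fp.weights
        n += 1
    if n == 0:
        raise ValueError("no footprints to accumulate")
    s = total.sum()
    if s <= 0:
        raise ValueError("all footprints are empty on this grid")
    return ACFC(grid=grid, weights=total / s, n_contributing=n)


def _boundary_cells(mask: np.ndarray) -> np.ndarray:
    """Cells of the mask touching its outside (4-connected erosion residue)."""
    eroded = ndimage.binary_erosion(mask, structure=np.array(
        [[0, 1, 0], [1, 1, 1], [0, 1, 0]]), border_value=0)
    return mask & ~eroded


def _trace_polylines(mask: np.ndarray, grid: GridSpec) -> list[np.ndarray]:
    lines = []
    for contour in measure.find_contours(mask.astype(float), 0.5):
        x = grid.x_centers[0] + contour[:, 1] * grid.cell_size
        y = grid.y_centers[0] - contour[:, 0] * grid.cell_size
        lines.append(np.column_stack([x, y]))
    return lines


def extract_contours(
    acfc: ACFC,
    levels: Iterable[int] = DEFAULT_LEVELS,
    fetch_level: int = 80,
) -> ContourSet:
    """Percentile source-area masks, areas, fetch and symmetry index.

    For each level r the enclosed cell set is the smallest-count set of
    highest-weight cells whose summed weight reaches r/100, with ties
    broken by (weight desc, row, col).
    """
    levels = sorted(int(r) for r in levels)
    for r in levels:
        if not 0 < r < 100:
            raise ValueError(f"contour level {r} outside (0, 100)")
    w = acfc.weights
    n = acfc.grid.n
    rows, cols = np.unravel_index(np.arange(w.size), w.shape)
    order = np.lexsort((cols, rows, -w.ravel()))
    csum = np.cumsum(w.ravel()[order])

    cell_area = acfc.grid.cell_size**2
    out: dict[int, ContourLevel] = {}
    for r in levels:
        k = int(np.searchsorted(csum, r / 100.0 - 1e-12)) + 1
        k = min(k, w.size)
        mask = np.zeros(w.size, dtype=bool)
        mask[order[:k]] = True
        mask = mask.reshape(w.shape)
        out[r] = ContourLevel(level=r, mask=mask, area_m2=k * cell_area,
                              polylines=_trace_polylines(mask, acfc.grid))

    fl = fetch_level if fetch_level in out else levels[-1]
    bmask = _boundary_cells(out[fl].mask)
    X, Y = acfc.grid.meshgrid()
    dist = np.hypot(X[bmask], Y[bmask])
    if dist.size == 0 or dist.max() == 0:
        log.warning("degenerate %d%% contour; fetch set to one cell", fl)
        fetch = acfc.grid.cell_size
    else:
        fetch = float(dist.max())
    si = symmetry_index(out[fl].area_m2, fetch)
    return ContourSet(grid=acfc.grid, levels=out, fetch_m=fetch, si=si)


def symmetry_index(area_m2: float, fetch_m: float) -> float:
    """SI = A / (π · fetch²): 1 for a tower-centred disc, < 1 otherwise."""
    if fetch_m <= 0:
        raise ValueError("fetch must be positive")
    return area_m2 / (math.pi * fetch_m**2)
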