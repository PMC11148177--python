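"""Surface-heterogeneity analysis: NDVI and semivariograms.

NDVI = (NIR − red)/(NIR + red) fields are composited annually (scenes with
≥ 5 % cloud are dropped), then the spatial structure of the surface inside
the 80 % footprint-climatology contour is summarised by empirical
semivariograms in four directions (E-W, NE-SW, N-S, NW-SE; ±22.5° angular
tolerance so the sectors tile the plane), averaged to an omnidirectional
estimate, and fitted with a spherical model to report nugget, sill and
range.

Two estimator modes are provided: the classical unweighted estimator
γ̂(h) = Σ (z_α − z_β)² / (2 N(h)), and a footprint-weighted variant where
each pair carries weight φ_α·φ_β (normalized per lag).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .rasters import ContinuousRaster

log = logging.getLogger(__name__)

__all__ = [
    "DIRECTIONS",
    "VariogramEstimate",
    "SphericalFit",
    "compute_ndvi",
    "annual_composite",
    "directional_semivariogram",
    "omnidirectional",
    "fit_spherical",
    "spherical_model",
]

#: direction name -> azimuth (deg clockwise from north) of the pair axis
DIRECTIONS: dict[str, float] = {
    "NS": 0.0,
    "NE-SW": 45.0,
    "EW": 90.0,
    "NW-SE": 135.0,
}

ANGULAR_TOL = 22.5  # deg; the four sectors tile the half-plane


@dataclass
class VariogramEstimate:
    """Empirical semivariogram for one direction (or the omnidirectional mean)."""

    direction: str
    lags: np.ndarray            # lag-bin centres, m
    gamma: np.ndarray           # γ̂(h); NaN where a bin has no pairs
    counts: np.ndarray          # pair counts N(h)
    weighted: bool = False

    def valid(self) -> "VariogramEstimate":
        """Copy restricted to lags with at least one pair."""
        ok = self.counts > 0
        return VariogramEstimate(self.direction, self.lags[ok], self.gamma[ok],
                                 self.counts[ok], self.weighted)


@dataclass
class SphericalFit:
    """Spherical-model parameters fitted to an empirical semivariogram."""

    nugget: float
    sill: float
    range_m: float
    nugget_sill_ratio: float    # percent, 100·nugget/sill
    rss: float = math.nan
    degenerate: bool = False


def compute_ndvi(nir: ContinuousRaster, red: ContinuousRaster) -> ContinuousRaster:
    """Cell-wise NDVI; cells where NIR + red = 0 (or either band is nodata) are masked."""
    if nir.grid != red.grid:
        raise ValueError("NIR and red bands are not co-registered")
    denom = nir.values + red.values
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = (nir.values - red.values) / denom
    vals = np.where(denom == 0, np.nan, vals)
    return ContinuousRaster(nir.grid, vals)


def annual_composite(
    scenes: list[tuple[ContinuousRaster, float]],
    cloud_threshold: float = 5.0,
) -> ContinuousRaster:
    """Cell-wise mean of scenes with cloud cover strictly below the threshold."""
    if not scenes:
        raise ValueError("no scenes to composite")
    keep = [r for r, cloud in scenes if cloud < cloud_threshold]
    if not keep:
        raise ValueError("all scenes dropped by the cloud filter")
    grid = keep[0].grid
    if any(r.grid != grid for r in keep):
        raise ValueError("scenes are not co-registered")
    stack = np.stack([r.values for r in keep])
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(stack, axis=0)
    return ContinuousRaster(grid, mean)


def _sector_of(dx: float, dy: float) -> str:
    """Direction sector of an offset vector (dx east, dy north).

    Azimuth folded into [0, 180); each sector owns [centre−22.5°, centre+22.5°)
    so the four sectors tile the plane with no overlap.
    """
    az = math.degrees(math.atan2(dx, dy)) % 180.0
    for name, centre in DIRECTIONS.items():
        lo = (centre - ANGULAR_TOL) % 180.0
        hi = centre + ANGULAR_TOL
        if centre == 0.0:
            if az >= lo or az < hi:
                return name
        elif lo <= az < hi:
            return name
    raise AssertionError("sectors should tile the plane")  # pragma: no cover


def directional_semivariogram(
    values: np.ndarray,
    mask: np.ndarray,
    cell_size: float,
    direction: str,
    weights: np.ndarray | None = None,
    max_lag_m: float | None = None,
) -> VariogramEstimate:
    """Empirical semivariogram of masked grid values along one direction.

    Pairs are cell pairs whose separation vector falls in the direction's
    ±22.5° sector; lag bins are one cell wide (bin centre = nearest integer
    multiple of ``cell_size``).  With ``weights`` given, each pair carries
    weight φ_α·φ_β and γ̂(h) is the weighted half-mean of squared
    differences (weights normalized per lag); without, the estimator is the
    classical unweighted one.

    ``direction`` may also be "omni": all sectors pooled.
    """
    if direction != "omni" and direction not in DIRECTIONS:
        raise ValueError(f"unknown direction {direction!r}")
    values = np.asarray(values, dtype=float)
    mask = np.asarray(mask, dtype=bool) & np.isfinite(values)
    if mask.sum() < 2:
        raise ValueError("need at least 2 unmasked cells")
    rows, cols = np.nonzero(mask)
    if max_lag_m is None:
        h_box = (rows.max() - rows.min()) * cell_size
        w_box = (cols.max() - cols.min()) * cell_size
        max_lag_m = 0.5 * math.hypot(h_box, w_box)
    # restrict the shift arithmetic to the mask bounding box
    sl = np.s_[rows.min():rows.max() + 1, cols.min():cols.max() + 1]
    values = values[sl]
    mask = mask[sl]
    if weights is not None:
        weights = np.asarray(weights, dtype=float)[sl]
    max_cells = max(1, int(math.floor(max_lag_m / cell_size)))

    nbins = max_cells + 1
    num = np.zeros(nbins)
    den = np.zeros(nbins)
    cnt = np.zeros(nbins, dtype=np.int64)

    weighted = weights is not None
    w = np.asarray(weights, dtype=float) if weighted else None

    nrow, ncol = values.shape
    for dj in range(0, max_cells + 1):          # column offset (east)
        di_range = range(1, max_cells + 1) if dj == 0 else range(-max_cells, max_cells + 1)
        for di in di_range:                     # row offset (south)
            dist = math.hypot(di, dj) * cell_size
            b = int(round(dist / cell_size))
            if b > max_cells or b == 0:
                continue
            if direction != "omni":
                # dx east = dj*cell, dy north = -di*cell
                if _sector_of(dj, -di) != direction:
                    continue
            r0, r1 = max(0, -di), min(nrow, nrow - di)
            c0, c1 = max(0, -dj), min(ncol, ncol - dj)
            if r0 >= r1 or c0 >= c1:
                continue
            a = np.s_[r0:r1, c0:c1]
            bsl = np.s_[r0 + di:r1 + di, c0 + dj:c1 + dj]
            both = mask[a] & mask[bsl]
            if not both.any():
                continue
            d2 = (values[a][both] - values[bsl][both]) ** 2
            if weighted:
                pw = w[a][both] * w[bsl][both]
                num[b] += float((pw * d2).sum())
                den[b] += float(pw.sum())
            else:
                num[b] += float(d2.sum())
                den[b] += both.sum()
            cnt[b] += int(both.sum())

    lags = np.arange(nbins) * cell_size
    with np.errstate(invalid="ignore", divide="ignore"):
        gamma = 0.5 * num / den
    gamma[cnt == 0] = np.nan
    est = VariogramEstimate(direction=direction, lags=lags[1:], gamma=gamma[1:],
                            counts=cnt[1:], weighted=weighted)
    if not np.any(est.counts > 0):
        raise ValueError("no pairs found at any lag")
    return est


def omnidirectional(estimates: list[VariogramEstimate]) -> VariogramEstimate:
    """Per-lag arithmetic mean of directional semivariograms."""
    if not estimates:
        raise ValueError("no directional estimates")
    lags = estimates[0].lags
    for e in estimates[1:]:
        if len(e.lags) != len(lags) or not np.allclose(e.lags, lags):
            raise ValueError("directional estimates have mismatched lag grids")
    gam = np.stack([e.gamma for e in estimates])
    cnt = np.stack([e.counts for e in estimates])
    return VariogramEstimate(
        direction="omni",
        lags=lags,
        gamma=gam.mean(axis=0),          # NaN propagates when any direction lacks pairs
        counts=cnt.sum(axis=0),
        weighted=estimates[0].weighted,
    )


def spherical_model(h: np.ndarray, nugget: float, sill: float, range_m: float) -> np.ndarray:
    """γ(h) = nugget + (sill−nugget)·(1.5 h/a − 0.5 (h/a)³) for h < a, sill beyond."""
    h = np.asarray(h, dtype=float)
    u = np.minimum(h / range_m, 1.0)
    return nugget + (sill - nugget) * (1.5 * u - 0.5 * u**3)


def fit_spherical(variogram: VariogramEstimate) -> SphericalFit:
    """Weighted least-squares spherical fit (weights = pair counts).

    Parameterized as (nugget, partial sill ≥ 0, range > 0) so the
    constraint 0 ≤ nugget ≤ sill holds by construction.  Initialisation:
    nugget from the first lag, sill from the mean of the last third, range
    from the first lag reaching 95 % of the sill estimate.
    """
    est = variogram.valid()
    ok = np.isfinite(est.gamma)
    h, g, n = est.lags[ok], est.gamma[ok], est.counts[ok]
    if len(h) < 4:
        raise ValueError("need at least 4 lags with pairs to fit")

    sill0 = float(np.mean(g[-max(1, len(g) // 3):]))
    nug0 = float(np.clip(g[0], 0.0, sill0))
    if sill0 <= 0:
        # constant field: γ̂ ≡ 0
        return SphericalFit(0.0, 0.0, float(h[0]), 0.0, rss=0.0, degenerate=True)
    reach = np.nonzero(g >= 0.95 * sill0)[0]
    a0 = float(h[reach[0]]) if len(reach) else float(h[-1])
    a0 = max(a0, float(h[0]))

    wts = np.sqrt(n / n.max())

    def resid(p):
        nug, psill, a = p
        return wts * (spherical_model(h, nug, nug + psill, a) - g)

    lo = [0.0, 0.0, float(h[0])]
    hi = [np.inf, np.inf, np.inf]
    x0 = [nug0, max(sill0 - nug0, 1e-12), a0]
    scale = [max(sill0, 1e-12), max(sill0, 1e-12), max(a0, float(h[0]))]
    sol = least_squares(resid, x0, bounds=(lo, hi), x_scale=scale,
                        xtol=1e-15, ftol=1e-15, gtol=1e-15)
    if not sol.success:
        raise RuntimeError(f"spherical fit did not converge: {sol.message}")
    nug, psill, a = sol.x
    sill = nug + psill
    ratio = 100.0 * nug / sill if sill > 0 else 0.0
    degenerate = a <= h[0] * (1 + 1e-9) or psill <= 1e-12 * max(sill, 1e-30)
    if degenerate:
        log.warning("spherical fit degenerate (range at lower bound or flat variogram)")
    return SphericalFit(float(nug), float(sill), float(a), float(ratio),
                        rss=float(2 * sol.cost), degenerate=degenerate)
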