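"""Sensor location bias and the three-indicator representativeness rating.

The footprint-weighted NDVI, NDVI_fp = Σ φ_j · NDVI_j (weights renormalized
over the 80 % contour), is compared with the unweighted mean NDVI of a
target area through the sensor location bias
SLB = (NDVI_fp − NDVI_target) / NDVI_target.  Targets are the 80 % contour
itself and a ladder of tower-centred square windows of side
l_i = 30·(2i − 1) m, i = 1..50 (30 m to 2970 m).

Each site is then rated on three indicators (1 High / 2 Medium / 3 Low):
dominant-cover percentage, omnidirectional nugget/sill ratio, and |SLB|
against the 80 % contour.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .rasters import ContinuousRaster, GridSpec

log = logging.getLogger(__name__)

__all__ = [
    "SLBResult",
    "WindowProfile",
    "SiteClassification",
    "footprint_weighted_ndvi",
    "target_mean_ndvi",
    "sensor_location_bias",
    "window_profile",
    "classify_site",
    "window_side",
]


@dataclass
class SLBResult:
    ndvi_fp: float
    ndvi_target: float
    slb: float | None           # None when the target mean is zero
    abs_slb: float | None


@dataclass
class WindowProfile:
    """Mean NDVI and SLB for the tower-centred square-window ladder."""

    sides_m: np.ndarray
    target_means: np.ndarray
    slb: np.ndarray
    ndvi_fp: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "window_side_m": self.sides_m,
            "ndvi_target": self.target_means,
            "ndvi_fp": self.ndvi_fp,
            "slb": self.slb,
            "abs_slb": np.abs(self.slb),
        })


@dataclass
class SiteClassification:
    """Three 1/2/3 ratings: cover dominance (rp), spatial structure (rs), bias (rb)."""

    rp: int
    rs: int
    rb: int


def window_side(i: int) -> float:
    """Side length l_i = 30·(2i − 1) m of the i-th square window."""
    if i < 1:
        raise ValueError("window index starts at 1")
    return 30.0 * (2 * i - 1)


def footprint_weighted_ndvi(
    weights: np.ndarray,
    mask: np.ndarray,
    grid: GridSpec,
    ndvi: ContinuousRaster,
) -> float:
    """NDVI_fp = Σ φ_j · NDVI_j with φ renormalized over the masked cells.

    Footprint cells whose centre falls on NDVI nodata (or outside the
    raster) are dropped before renormalizing.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty footprint mask")
    X, Y = grid.meshgrid()
    vals = ndvi.sample(X[mask], Y[mask])
    w = np.asarray(weights, dtype=float)[mask]
    ok = np.isfinite(vals)
    if not ok.any() or w[ok].sum() <= 0:
        raise ValueError("footprint mask does not overlap valid NDVI data")
    w = w[ok] / w[ok].sum()
    return float((w * vals[ok]).sum())


def target_mean_ndvi(
    mask: np.ndarray,
    grid: GridSpec,
    ndvi: ContinuousRaster,
) -> float:
    """Unweighted mean NDVI over the cells of a target mask."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty target mask")
    X, Y = grid.meshgrid()
    vals = ndvi.sample(X[mask], Y[mask])
    ok = np.isfinite(vals)
    if not ok.any():
        raise ValueError("target mask does not overlap valid NDVI data")
    return float(vals[ok].mean())


def sensor_location_bias(ndvi_fp: float, ndvi_target: float) -> SLBResult:
    """SLB = (NDVI_fp − NDVI_target) / NDVI_target; undefined at target 0."""
    if ndvi_target == 0:
        log.warning("SLB undefined: target-area mean NDVI is zero")
        return SLBResult(ndvi_fp, ndvi_target, None, None)
    slb = (ndvi_fp - ndvi_target) / ndvi_target
    return SLBResult(ndvi_fp, ndvi_target, slb, abs(slb))


def window_profile(
    ndvi: ContinuousRaster,
    ndvi_fp: float,
    n_windows: int = 50,
) -> WindowProfile:
    """Mean NDVI and SLB for tower-centred squares of side 30·(2i−1) m.

    Window membership is a cell-centre test.  Windows larger than the
    raster extent are truncated to it (with a warning).
    """
    g = ndvi.grid
    X, Y = g.meshgrid()
    cheb = np.maximum(np.abs(X), np.abs(Y))
    sides = np.array([window_side(i) for i in range(1, n_windows + 1)])
    if sides[-1] / 2.0 > g.half_width:
        log.warning("largest window (%.0f m) exceeds the raster extent; truncated",
                    sides[-1])
    means = np.empty(n_windows)
    slb = np.empty(n_windows)
    for k, side in enumerate(sides):
        sel = (cheb <= side / 2.0) & ndvi.mask
        means[k] = ndvi.values[sel].mean() if sel.any() else np.nan
        res = sensor_location_bias(ndvi_fp, means[k]) if np.isfinite(means[k]) else None
        slb[k] = res.slb if res is not None and res.slb is not None else np.nan
    return WindowProfile(sides_m=sides, target_means=means, slb=slb, ndvi_fp=ndvi_fp)


def classify_site(
    dominant_pct: float,
    nugget_sill_ratio_pct: float,
    abs_slb: float,
) -> SiteClassification:
    """Three-band rating of the three indicators.

    Cover: < 50 % → 3, 50–80 % → 2, > 80 % → 1.
    Nugget/sill: < 25 % → 1, 25–75 % → 2, > 75 % → 3.
    |SLB|: < 0.05 → 1, 0.05–0.1 → 2, > 0.1 → 3.
    Band boundaries belong to the middle band.
    """
    for name, v in (("dominant_pct", dominant_pct),
                    ("nugget_sill_ratio_pct", nugget_sill_ratio_pct),
                    ("abs_slb", abs_slb)):
        if not np.isfinite(v):
            raise ValueError(f"{name} is not finite")
    if not 0.0 <= nugget_sill_ratio_pct <= 100.0:
        raise ValueError("nugget/sill ratio must be within [0, 100] percent")
    if abs_slb < 0:
        raise ValueError("abs_slb must be non-negative")

    rp = 3 if dominant_pct < 50 else (2 if dominant_pct <= 80 else 1)
    rs = 1 if nugget_sill_ratio_pct < 25 else (2 if nugget_sill_ratio_pct <= 75 else 3)
    rb = 1 if abs_slb < 0.05 else (2 if abs_slb <= 0.1 else 3)
    return SiteClassification(rp=rp, rs=rs, rb=rb)
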