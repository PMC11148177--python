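"""Two-dimensional flux-footprint parameterization (FFP).

Implements the widely used two-dimensional parameterization of the flux
footprint for surface-layer eddy-covariance measurements: the scaled
crosswind-integrated footprint follows a power-law × exponential curve in a
non-dimensional upwind distance, with the published fitted constants, and
the crosswind spread is Gaussian with a parameterized σ_y(x).  The
streamwise axis is rotated so the source area lies toward the
meteorological wind direction (the bearing the wind blows *from*) as seen
from the tower.

Validity of the parameterization is restricted to
zm/L ≥ −15.5 and 20·z0 < zm < 0.8·pblh (zm above the displacement height);
records outside those bounds are refused with the violated rule named.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .micromet import (
    HalfHourRecord,
    SiteMeta,
    check_validity,
    estimate_pblh,
    record_obukhov,
)
from .rasters import GridSpec

__all__ = [
    "FootprintGrid",
    "halfhour_footprint",
    "crosswind_integrated_profile",
    "FootprintInvalidError",
]

# published fitted constants of the parameterization
A_CONST = 1.4524
B_CONST = -1.9914
C_CONST = 1.4622
D_CONST = 0.1359
AC_CONST = 2.17
BC_CONST = 1.66
CC_CONST = 20.0

OLN = 5000.0  # |L| beyond which the stratification is treated as neutral
VON_KARMAN = 0.4


class FootprintInvalidError(ValueError):
    """Record violates the parameterization's validity bounds."""

    def __init__(self, rule: str):
        self.rule = rule
        super().__init__(f"record violates footprint validity rule: {rule}")


@dataclass
class FootprintGrid:
    """Half-hourly footprint density f(x, y) [m⁻²] on a tower-centred grid."""

    grid: GridSpec
    weights: np.ndarray
    meta: dict

    @property
    def total(self) -> float:
        """Integral of the density over the grid (≤ 1)."""
        return float(self.weights.sum() * self.grid.cell_size**2)


def _psi_m(zm: float, L: float) -> float:
    """Integrated stability correction for the wind profile."""
    if L >= OLN:
        return 0.0
    if L > 0:
        return -5.3 * zm / L
    xx = (1.0 - 19.0 * zm / L) ** 0.25
    return (math.log((1.0 + xx**2) / 2.0) + 2.0 * math.log((1.0 + xx) / 2.0)
            - 2.0 * math.atan(xx) + math.pi / 2.0)


def _scaling(zm: float, z0: float, L: float, pblh: float) -> tuple[float, float]:
    """(x-scale, f-scale): x = X*·xscale and f_ci = F*·fscale."""
    psi = _psi_m(zm, L)
    log_term = math.log(zm / z0) - psi
    if log_term <= 0:
        raise FootprintInvalidError("wind_profile")
    xscale = zm / (1.0 - zm / pblh) * log_term
    return xscale, 1.0 / xscale


def fstar(xstar: np.ndarray) -> np.ndarray:
    """Scaled crosswind-integrated footprint F*(X*) with the published constants."""
    xstar = np.asarray(xstar, dtype=float)
    out = np.zeros_like(xstar)
    ok = xstar > D_CONST
    t = xstar[ok] - D_CONST
    out[ok] = A_CONST * t**B_CONST * np.exp(-C_CONST / t)
    return out


def _sigma_y(xstar: np.ndarray, zm: float, L: float, sigma_v: float,
             ustar: float) -> np.ndarray:
    """Parameterized crosswind spread σ_y(x) on the real scale."""
    xstar = np.asarray(xstar, dtype=float)
    sigystar = AC_CONST * np.sqrt(
        BC_CONST * xstar**2 / (1.0 + CC_CONST * np.maximum(xstar, 0.0)))
    if abs(L) > OLN:
        L = -1e6
    if L <= 0:
        scale_const = 1e-5 * abs(zm / L) ** (-1) + 0.80
    else:
        scale_const = 1e-5 * abs(zm / L) ** (-1) + 0.55
    scale_const = min(scale_const, 1.0)
    return sigystar / scale_const * zm * sigma_v / ustar


def _resolve_drivers(record: HalfHourRecord, meta: SiteMeta,
                     convective_pblh: float) -> tuple[float, float, float, float]:
    """(zm_eff, z0, L, pblh) for the record, validity-checked."""
    z0, d = meta.roughness_at(record.timestamp)
    zm_eff = meta.zm - d
    L = record_obukhov(record)
    pblh = estimate_pblh(record, meta.lat, convective_pblh)
    rule = check_validity(record, zm_eff, z0, pblh, L)
    if rule is not None:
        raise FootprintInvalidError(rule)
    return zm_eff, z0, L, pblh


def crosswind_integrated_profile(
    record: HalfHourRecord,
    meta: SiteMeta,
    x: np.ndarray,
    convective_pblh: float = 2000.0,
) -> np.ndarray:
    """Crosswind-integrated footprint f_y(x) [m⁻¹] at upwind distances ``x``."""
    zm, z0, L, pblh = _resolve_drivers(record, meta, convective_pblh)
    xscale, fscale = _scaling(zm, z0, L, pblh)
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    pos = x > 0
    out[pos] = fstar(x[pos] / xscale) * fscale
    return out


def halfhour_footprint(
    record: HalfHourRecord,
    meta: SiteMeta,
    grid: GridSpec | None = None,
    convective_pblh: float = 2000.0,
) -> FootprintGrid:
    """Two-dimensional footprint density for one averaging interval.

    The upwind (streamwise) axis points toward bearing ``record.wd`` from
    the tower; the crosswind profile is Gaussian with parameterized
    σ_y(x).  Over an unbounded domain the density integrates to 1; on the
    finite grid the integral is ≤ 1.
    """
    if grid is None:
        grid = GridSpec(cell_size=10.0, half_width=2000.0)
    if record.sigma_v is None or not np.isfinite(record.sigma_v):
        raise ValueError("record has no sigma_v; fill it before footprint modelling")
    zm, z0, L, pblh = _resolve_drivers(record, meta, convective_pblh)
    xscale, fscale = _scaling(zm, z0, L, pblh)

    X, Y = grid.meshgrid()
    theta = math.radians(record.wd)
    # streamwise coordinate grows toward the "from" bearing; crosswind is
    # the perpendicular (sign immaterial: the crosswind model is symmetric)
    xs = X * math.sin(theta) + Y * math.cos(theta)
    ys = X * math.cos(theta) - Y * math.sin(theta)

    weights = np.zeros_like(xs)
    pos = xs > 0
    xstar = xs[pos] / xscale
    f_ci = fstar(xstar) * fscale
    sy = _sigma_y(xstar, zm, L, record.sigma_v, record.ustar)
    good = sy > 0
    vals = np.zeros_like(f_ci)
    vals[good] = f_ci[good] * np.exp(-0.5 * (ys[pos][good] / sy[good]) ** 2) / (
        math.sqrt(2.0 * math.pi) * sy[good])
    weights[pos] = vals
    return FootprintGrid(grid=grid, weights=weights, meta={
        "zm": zm, "z0": z0, "ws": record.ws, "wd": record.wd,
        "ustar": record.ustar, "sigma_v": record.sigma_v, "L": L, "pblh": pblh,
    })
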