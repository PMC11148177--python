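"""Synthetic scene generation.

Emulates the inputs the pipeline normally takes from flux-network archives
and satellite products: half-hourly micrometeorology with a prescribed wind
rose and stability mix, a patchy categorical land-cover raster, an NDVI
field with a prescribed spherical spatial covariance, and a σ_v training
table with a documented generating function so the attainable predictor
skill is computable in closed form.

Every generator is a pure function of its configuration (including the
seed); there is no global random state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .landcover import GLC_FCS30_TO_IGBP
from .micromet import HalfHourRecord, obukhov_length
from .rasters import CategoricalRaster, ContinuousRaster, GridSpec

__all__ = [
    "SceneConfig",
    "gen_met_series",
    "gen_landcover_raster",
    "gen_ndvi_field",
    "gen_sigma_v_training",
    "sigma_v_signal",
    "noise_sd_for_r2",
    "attainable_r2",
]

# eight-sector wind rose with a mild westerly preference
_DEFAULT_ROSE = [
    (0.0, 0.10), (45.0, 0.10), (90.0, 0.10), (135.0, 0.10),
    (180.0, 0.10), (225.0, 0.15), (270.0, 0.25), (315.0, 0.10),
]

_DEFAULT_PATCHES = [
    (130, {"shape": "all"}),                                        # grassland base
    (60, {"shape": "disc", "cx": -500.0, "cy": 300.0, "r": 250.0}),  # deciduous forest
    (10, {"shape": "rect", "xmin": 1200.0, "xmax": 1980.0,
          "ymin": -1980.0, "ymax": 1980.0}),                         # cropland strip
]


@dataclass
class SceneConfig:
    """Configuration of a synthetic tower scene.

    The defaults describe a moderately heterogeneous grassland tower:
    a ±1980 m window (≈ ±0.02° of latitude) with 30 m land cover and 10 m
    NDVI, a westerly-skewed wind rose, a (0.5, 0.3, 0.2)
    unstable/neutral/stable mix, and NDVI spatial structure with nugget
    2e-4, sill 1e-3 and range 240 m.
    """

    seed: int = 0
    n_halfhours: int = 8000
    wind_rose: Sequence[tuple[float, float]] = tuple(_DEFAULT_ROSE)
    stability_mix: tuple[float, float, float] = (0.5, 0.3, 0.2)
    raster_extent: float = 1980.0           # half-width, m
    cell_sizes: tuple[float, float] = (30.0, 10.0)  # (landcover, ndvi), m
    variogram_truth: tuple[float, float, float] = (2e-4, 1e-3, 240.0)
    landcover_patches: Sequence[tuple[int, dict]] = tuple(_DEFAULT_PATCHES)
    ndvi_mean: float = 0.45
    measured_sigma_v_fraction: float = 0.3
    wd_jitter_deg: float = 12.0

    def __post_init__(self) -> None:
        probs = [p for _, p in self.wind_rose]
        if abs(sum(probs) - 1.0) > 1e-9 or any(p < 0 for p in probs):
            raise ValueError("wind rose probabilities must be >=0 and sum to 1")
        if abs(sum(self.stability_mix) - 1.0) > 1e-9 or any(p < 0 for p in self.stability_mix):
            raise ValueError("stability mix fractions must be >=0 and sum to 1")
        nugget, sill, rng = self.variogram_truth
        if nugget < 0 or sill < nugget or rng <= 0:
            raise ValueError("variogram truth requires 0 <= nugget <= sill and range > 0")
        for cell in self.cell_sizes:
            ratio = 2.0 * self.raster_extent / cell
            if abs(ratio - round(ratio)) > 1e-9:
                raise ValueError(f"cell size {cell} m must divide the raster extent")
        for code, _ in self.landcover_patches:
            if code not in GLC_FCS30_TO_IGBP:
                raise ValueError(f"unknown land-cover class code {code}")

    @property
    def landcover_grid(self) -> GridSpec:
        return GridSpec(cell_size=self.cell_sizes[0], half_width=self.raster_extent)

    @property
    def ndvi_grid(self) -> GridSpec:
        return GridSpec(cell_size=self.cell_sizes[1], half_width=self.raster_extent)


def gen_met_series(config: SceneConfig) -> list[HalfHourRecord]:
    """Half-hourly met drivers with the configured wind rose and stability mix.

    Wind speed is lognormal; u* follows a log-law-like fraction of WS with
    noise; the Obukhov length is drawn per stability regime (unstable L < 0,
    stable L > 0, neutral |L| large) and the sensible heat flux is back-
    computed from L so the drivers are physically consistent.  σ_v is set
    from the documented generating function for a configurable fraction of
    records and left missing otherwise.
    """
    if config.n_halfhours < 1:
        raise ValueError("n_halfhours must be >= 1")
    rng = np.random.default_rng(config.seed)
    n = config.n_halfhours
    times = pd.date_range("2015-01-01 00:00", periods=n, freq="30min")

    bearings = np.array([b for b, _ in config.wind_rose])
    probs = np.array([p for _, p in config.wind_rose])
    sector = rng.choice(len(bearings), size=n, p=probs)
    wd = (bearings[sector] + rng.normal(0.0, config.wd_jitter_deg, n)) % 360.0

    ws = np.clip(rng.lognormal(mean=1.0, sigma=0.45, size=n), 0.5, 15.0)
    ustar = np.clip(0.07 + 0.065 * ws * (1.0 + 0.15 * rng.normal(size=n)), 0.05, 1.5)

    regime = rng.choice(3, size=n, p=list(config.stability_mix))  # 0 unst, 1 neut, 2 stab
    absL = np.where(
        regime == 1,
        10 ** rng.uniform(3.3, 3.69, n),     # neutral: |L| 2000-4900 m
        10 ** rng.uniform(1.0, 2.7, n),      # unstable/stable: 10-500 m
    )
    sign = np.where(regime == 0, -1.0, np.where(regime == 2, 1.0,
                    np.where(rng.random(n) < 0.5, -1.0, 1.0)))
    L = sign * absL

    hour = times.hour + times.minute / 60.0
    doy = times.dayofyear.to_numpy()
    sw_in = np.clip(900.0 * np.sin(np.pi * (hour - 6.0) / 12.0), 0.0, None)
    sw_in *= 0.75 + 0.25 * rng.random(n)
    ta = 8.0 + 12.0 * np.sin(2 * np.pi * (doy - 110) / 365.25) + 4.0 * np.sin(
        np.pi * (hour - 9.0) / 12.0) + rng.normal(0.0, 1.0, n)
    pa = rng.normal(98.0, 0.6, n)

    # back out H from L for consistency: H = -rho cp T u*^3 / (k g L)
    t_k = ta + 273.15
    rho = pa * 1000.0 / (287.05 * t_k)
    h_flux = -rho * 1004.0 * t_k * ustar**3 / (0.4 * 9.81 * L)

    sig_frame = pd.DataFrame({
        "USTAR": ustar, "WS": ws, "SW_IN": sw_in, "PA": pa,
        "Z0": np.full(n, 0.03), "HM": np.full(n, 3.0), "HC": np.full(n, 0.3),
    })
    sigma_v = sigma_v_signal(sig_frame) + rng.normal(0.0, 0.05, n)
    sigma_v = np.clip(sigma_v, 0.05, None)
    has_sigma = rng.random(n) < config.measured_sigma_v_fraction

    records = []
    for i in range(n):
        records.append(HalfHourRecord(
            timestamp=times[i], ws=float(ws[i]), wd=float(wd[i]),
            ustar=float(ustar[i]),
            sigma_v=float(sigma_v[i]) if has_sigma[i] else None,
            L=float(L[i]), pblh=None,
            sw_in=float(sw_in[i]), pa=float(pa[i]), ta=float(ta[i]),
            h=float(h_flux[i]),
        ))
    return records


def _paint(codes: np.ndarray, grid: GridSpec, code: int, spec: dict) -> None:
    X, Y = grid.meshgrid()
    shape = spec.get("shape", "all")
    if shape == "all":
        codes[:] = code
    elif shape == "halfplane":
        b = math.radians(spec["bearing"])
        offset = spec.get("offset", 0.0)
        sel = X * math.sin(b) + Y * math.cos(b) >= offset
        codes[sel] = code
    elif shape == "disc":
        cx, cy, r = spec["cx"], spec["cy"], spec["r"]
        if abs(cx) + r > grid.half_width or abs(cy) + r > grid.half_width:
            raise ValueError("disc patch extends outside the raster extent")
        codes[(X - cx) ** 2 + (Y - cy) ** 2 <= r**2] = code
    elif shape == "rect":
        if max(abs(spec["xmin"]), abs(spec["xmax"]),
               abs(spec["ymin"]), abs(spec["ymax"])) > grid.half_width + 1e-9:
            raise ValueError("rect patch extends outside the raster extent")
        sel = ((X >= spec["xmin"]) & (X <= spec["xmax"])
               & (Y >= spec["ymin"]) & (Y <= spec["ymax"]))
        codes[sel] = code
    else:
        raise ValueError(f"unknown patch shape {shape!r}")


def gen_landcover_raster(config: SceneConfig) -> CategoricalRaster:
    """Patchy categorical raster; patches are painted in list order."""
    grid = config.landcover_grid
    codes = np.full((grid.n, grid.n), config.landcover_patches[0][0], dtype=np.int32)
    for code, spec in config.landcover_patches:
        _paint(codes, grid, code, spec)
    return CategoricalRaster(grid, codes)


def spherical_covariance(h: np.ndarray, partial_sill: float, range_m: float) -> np.ndarray:
    """Spherical covariance C(h) = psill·(1 − 1.5 h/a + 0.5 (h/a)³), 0 beyond a."""
    u = np.minimum(np.asarray(h, dtype=float) / range_m, 1.0)
    return partial_sill * (1.0 - 1.5 * u + 0.5 * u**3)


def gen_ndvi_field(config: SceneConfig) -> ContinuousRaster:
    """Gaussian random field with the configured spherical nugget/sill/range.

    The spatially structured part (partial sill = sill − nugget) is
    synthesised by circulant (FFT) embedding on a doubled torus — exact up
    to the truncation of any negative embedding eigenvalues — and iid
    Gaussian noise of variance ``nugget`` is added on top.  The field is
    shifted to ``ndvi_mean`` and clipped into [−1, 1].
    """
    nugget, sill, range_m = config.variogram_truth
    grid = config.ndvi_grid
    rng = np.random.default_rng(config.seed + 1)
    n = grid.n
    if sill == 0:
        return ContinuousRaster(grid, np.full((n, n), config.ndvi_mean))
    psill = sill - nugget
    field = np.zeros((n, n))
    if psill > 0:
        m = 2 * n
        idx = np.arange(m)
        lag = np.minimum(idx, m - idx) * grid.cell_size  # min-image distance on torus
        dist = np.hypot(lag[:, None], lag[None, :])
        kernel = spherical_covariance(dist, psill, range_m)
        lam = np.fft.fft2(kernel).real
        lam = np.clip(lam, 0.0, None)
        eps = rng.normal(size=(m, m))
        big = np.fft.ifft2(np.sqrt(lam) * np.fft.fft2(eps)).real
        field = big[:n, :n]
    if nugget > 0:
        field = field + rng.normal(0.0, math.sqrt(nugget), size=(n, n))
    return ContinuousRaster(grid, np.clip(field + config.ndvi_mean, -1.0, 1.0))


def sigma_v_signal(frame: pd.DataFrame) -> np.ndarray:
    """Documented noiseless generating function of σ_v [m s⁻¹].

    Affine in u* and WS with a mild u*·WS interaction, plus small smooth
    contributions from shortwave, pressure, roughness and the two heights.
    Fixing this function makes the attainable predictor R² computable from
    the configured noise variance.
    """
    return (
        1.75 * frame["USTAR"].to_numpy(dtype=float)
        + 0.06 * frame["WS"].to_numpy(dtype=float)
        + 0.10 * frame["USTAR"].to_numpy(dtype=float) * frame["WS"].to_numpy(dtype=float)
        + 1.5e-4 * frame["SW_IN"].to_numpy(dtype=float)
        + 0.004 * (frame["PA"].to_numpy(dtype=float) - 95.0)
        + 0.05 * np.log1p(10.0 * frame["Z0"].to_numpy(dtype=float))
        + 0.002 * (frame["HM"].to_numpy(dtype=float) - frame["HC"].to_numpy(dtype=float))
    )


def noise_sd_for_r2(signal: np.ndarray, r2: float) -> float:
    """Noise SD making signal-variance / total-variance equal ``r2``."""
    if not 0 < r2 <= 1:
        raise ValueError("target R2 must be in (0, 1]")
    var_s = float(np.var(signal))
    return math.sqrt(var_s * (1.0 - r2) / r2)


def attainable_r2(signal: np.ndarray, noise_sd: float) -> float:
    """Best possible predictor R² given the generator's noise SD."""
    var_s = float(np.var(signal))
    return var_s / (var_s + noise_sd**2)


def gen_sigma_v_training(
    config: SceneConfig,
    n: int = 20000,
    noise_sd: float | None = None,
    target_r2: float = 0.78,
) -> tuple[pd.DataFrame, float]:
    """σ_v training table over the 7 covariates, plus the attainable R².

    Covariates span multi-site ranges (roughness 1 cm–2 m, canopy 0.2–25 m).
    If ``noise_sd`` is None it is set so the attainable R² equals
    ``target_r2`` (default 0.78, a realistic cross-site skill level).
    """
    if n < 1000:
        raise ValueError("need at least 1000 training rows")
    rng = np.random.default_rng(config.seed + 2)
    ws = np.clip(rng.lognormal(1.0, 0.5, n), 0.3, 18.0)
    ustar = np.clip(0.07 + 0.065 * ws * (1.0 + 0.2 * rng.normal(size=n)), 0.05, 1.5)
    sw_in = rng.uniform(0.0, 1000.0, n) * (rng.random(n) < 0.55)
    pa = rng.normal(97.0, 3.0, n)
    hc = np.exp(rng.uniform(math.log(0.2), math.log(25.0), n))
    z0 = 0.1 * hc
    hm = hc * rng.uniform(1.3, 3.0, n) + rng.uniform(1.0, 5.0, n)
    frame = pd.DataFrame({
        "USTAR": ustar, "WS": ws, "SW_IN": sw_in, "PA": pa,
        "Z0": z0, "HM": hm, "HC": hc,
    })
    signal = sigma_v_signal(frame)
    if noise_sd is None:
        noise_sd = noise_sd_for_r2(signal, target_r2)
    frame["SIGMA_V"] = np.clip(signal + rng.normal(0.0, noise_sd, n), 1e-3, None)
    return frame, attainable_r2(signal, noise_sd)
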