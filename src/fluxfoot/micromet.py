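"""Per-interval micrometeorological drivers for footprint modelling.

Derives roughness parameters from canopy height, the Obukhov length from
the surface-layer flux-profile relationships, a diagnostic boundary-layer
height, applies the footprint model's validity filter, and fits/applies the
lateral-wind-fluctuation (σ_v) predictor used to fill sites that do not
report σ_v.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.metrics import mean_absolute_error, r2_score
from sklearn.model_selection import KFold

log = logging.getLogger(__name__)

__all__ = [
    "HalfHourRecord",
    "SiteMeta",
    "SigmaVModel",
    "FilterReport",
    "derive_roughness",
    "obukhov_length",
    "estimate_pblh",
    "qc_filter",
    "fit_sigma_v",
    "predict_sigma_v",
    "SIGMA_V_COVARIATES",
]

VON_KARMAN = 0.4
GRAVITY = 9.81          # m s-2
CP_AIR = 1004.0         # J kg-1 K-1
R_DRY = 287.05          # J kg-1 K-1
OMEGA_EARTH = 7.2921159e-5  # rad s-1

#: covariate column order expected by the σ_v predictor
SIGMA_V_COVARIATES = ["USTAR", "WS", "SW_IN", "PA", "Z0", "HM", "HC"]


@dataclass
class HalfHourRecord:
    """One eddy-covariance averaging interval's footprint drivers.

    ``wd`` is the meteorological wind direction: degrees clockwise from
    north of the direction the wind blows *from* (the source area lies at
    that bearing from the tower).
    """

    timestamp: pd.Timestamp
    ws: float | None = None          # m s-1
    wd: float | None = None          # deg, [0, 360)
    ustar: float | None = None       # m s-1
    sigma_v: float | None = None     # m s-1, may be absent
    L: float | None = None           # m, Obukhov length, may be absent
    pblh: float | None = None        # m, may be absent
    sw_in: float | None = None       # W m-2
    pa: float | None = None          # kPa
    ta: float | None = None          # deg C
    h: float | None = None           # W m-2, sensible heat flux

    @property
    def is_complete(self) -> bool:
        """True when the mandatory footprint drivers are all present."""
        mandatory = (self.ws, self.wd, self.ustar, self.pa, self.ta, self.h)
        return all(v is not None and np.isfinite(v) for v in mandatory)


@dataclass
class SiteMeta:
    """Static (or slowly varying) tower metadata.

    ``hc`` may be a scalar canopy height or a dated series
    ``[(timestamp, hc), ...]`` sorted ascending; z0/d are derived from the
    value in force unless given explicitly.
    """

    site_id: str
    igbp_code: int
    lat: float
    lon: float
    zm: float                      # measurement height above ground, m
    hc: float | Sequence[tuple[pd.Timestamp, float]] = 0.2
    z0: float | None = None
    d: float | None = None

    def hc_at(self, when: pd.Timestamp | None = None) -> float:
        if np.isscalar(self.hc):
            return float(self.hc)
        series = list(self.hc)
        if when is None:
            return float(series[0][1])
        value = series[0][1]
        for ts, hc in series:
            if pd.Timestamp(ts) <= when:
                value = hc
            else:
                break
        return float(value)

    def roughness_at(self, when: pd.Timestamp | None = None) -> tuple[float, float]:
        """(z0, d) in force at ``when``."""
        if self.z0 is not None and self.d is not None:
            return float(self.z0), float(self.d)
        return derive_roughness(self.hc_at(when))


@dataclass
class SigmaVModel:
    """Ensemble-regression predictor of σ_v over 7 micromet covariates."""

    regressor: RandomForestRegressor
    cv_folds: int
    cv_r2: float
    cv_mae: float
    fold_r2: list[float] = field(default_factory=list)

    def predict(self, frame: pd.DataFrame) -> np.ndarray:
        X = frame[SIGMA_V_COVARIATES].to_numpy(dtype=float)
        out = self.regressor.predict(X)
        # σ_v is a turbulence magnitude; never allow non-positive output
        return np.clip(out, 1e-3, None)


@dataclass
class FilterReport:
    n_input: int = 0
    n_kept: int = 0
    n_rejected_stability: int = 0
    n_rejected_height_low: int = 0
    n_rejected_height_high: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def derive_roughness(hc: float) -> tuple[float, float]:
    """Roughness length and displacement height from canopy height.

    z0 = 0.1·hc and d = 0.67·hc, the standard rule-of-thumb fractions.
    """
    if hc <= 0:
        raise ValueError("canopy height must be positive")
    return 0.1 * hc, 0.67 * hc


def obukhov_length(ustar: float, ta: float, pa: float, h: float) -> float:
    """Obukhov length L from friction velocity and sensible heat flux.

    L = −ρ c_p T u*³ / (k g H), with air density from the ideal gas law at
    (pa [kPa], ta [°C]).  Sign opposite to H: unstable (H > 0) gives L < 0.
    H = 0 returns +inf (neutral sentinel).
    """
    if ustar <= 0:
        raise ValueError("ustar must be positive")
    if h == 0:
        return math.inf
    t_k = ta + 273.15
    rho = pa * 1000.0 / (R_DRY * t_k)
    return -rho * CP_AIR * t_k * ustar**3 / (VON_KARMAN * GRAVITY * h)


def record_obukhov(record: HalfHourRecord) -> float:
    """L from the record, computing it from (ustar, ta, pa, h) when absent."""
    if record.L is not None and np.isfinite(record.L):
        return float(record.L)
    return obukhov_length(record.ustar, record.ta, record.pa, record.h)


def estimate_pblh(
    record: HalfHourRecord,
    lat: float,
    convective_default: float = 2000.0,
) -> float:
    """Boundary-layer height for the record.

    A measured value passes through.  For stable/neutral stratification
    (L > 0) the diagnostic equilibrium height
    h = (L/3.8)·(−1 + √(1 + 2.28·u*/(f·L))) is used, with f the Coriolis
    parameter at ``lat``.  Convective cases (L < 0) fall back to
    ``convective_default`` since the equilibrium diagnostic does not apply.
    """
    if record.pblh is not None and np.isfinite(record.pblh):
        return float(record.pblh)
    L = record_obukhov(record)
    if L <= 0 or not np.isfinite(L):
        return float(convective_default)
    if abs(lat) < 5.0:
        log.warning("Coriolis parameter too small at |lat|<5 deg; using convective default")
        return float(convective_default)
    f = 2.0 * OMEGA_EARTH * math.sin(math.radians(abs(lat)))
    return (L / 3.8) * (-1.0 + math.sqrt(1.0 + 2.28 * record.ustar / (f * L)))


#: lower bound on zm/L below which the footprint parameterization is invalid
STABILITY_BOUND = -15.5


def check_validity(
    record: HalfHourRecord,
    zm_eff: float,
    z0: float,
    pblh: float,
    L: float,
) -> str | None:
    """Name of the first violated validity rule, or None when valid.

    The rules are the footprint parameterization's published bounds:
    zm/L ≥ −15.5 and 20·z0 < zm < 0.8·pblh, applied with zm measured above
    the zero-plane displacement.
    """
    if zm_eff / L < STABILITY_BOUND:
        return "stability"
    if zm_eff <= 20.0 * z0:
        return "height_low"
    if zm_eff >= 0.8 * pblh:
        return "height_high"
    return None


def qc_filter(
    records: Iterable[HalfHourRecord],
    meta: SiteMeta,
    convective_default: float = 2000.0,
) -> tuple[list[HalfHourRecord], FilterReport]:
    """Keep records satisfying the footprint model's validity bounds.

    A record failing several rules is attributed to the first failed rule in
    the order: stability, lower height bound, upper height bound.
    """
    kept: list[HalfHourRecord] = []
    report = FilterReport()
    for rec in records:
        report.n_input += 1
        z0, d = meta.roughness_at(rec.timestamp)
        zm_eff = meta.zm - d
        L = record_obukhov(rec)
        pblh = estimate_pblh(rec, meta.lat, convective_default)
        rule = check_validity(rec, zm_eff, z0, pblh, L)
        if rule is None:
            report.n_kept += 1
            kept.append(rec)
        elif rule == "stability":
            report.n_rejected_stability += 1
        elif rule == "height_low":
            report.n_rejected_height_low += 1
        else:
            report.n_rejected_height_high += 1
    log.info(
        "qc_filter: kept %d of %d records (stability %d, height_low %d, height_high %d)",
        report.n_kept, report.n_input, report.n_rejected_stability,
        report.n_rejected_height_low, report.n_rejected_height_high,
    )
    return kept, report


def fit_sigma_v(training: pd.DataFrame, folds: int = 5, seed: int = 0) -> SigmaVModel:
    """Fit the σ_v predictor with k-fold cross-validation.

    ``training`` must carry the 7 covariate columns plus ``SIGMA_V``.  The
    predictor is a 100-tree random forest; the reported R² and MAE are
    computed on pooled out-of-fold predictions.
    """
    if folds < 2:
        raise ValueError("need at least 2 folds")
    missing = [c for c in SIGMA_V_COVARIATES + ["SIGMA_V"] if c not in training.columns]
    if missing:
        raise KeyError(f"training table missing columns: {missing}")
    X = training[SIGMA_V_COVARIATES].to_numpy(dtype=float)
    y = training["SIGMA_V"].to_numpy(dtype=float)

    oof = np.full(len(y), np.nan)
    fold_r2: list[float] = []
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    for train_idx, test_idx in kf.split(X):
        rf = RandomForestRegressor(n_estimators=100, random_state=seed, n_jobs=1)
        rf.fit(X[train_idx], y[train_idx])
        pred = rf.predict(X[test_idx])
        oof[test_idx] = pred
        fold_r2.append(r2_score(y[test_idx], pred))
    cv_r2 = r2_score(y, oof)
    cv_mae = mean_absolute_error(y, oof)

    final = RandomForestRegressor(n_estimators=100, random_state=seed, n_jobs=1)
    final.fit(X, y)
    log.info("fit_sigma_v: %d-fold CV R2=%.3f MAE=%.3f m s-1", folds, cv_r2, cv_mae)
    return SigmaVModel(regressor=final, cv_folds=folds, cv_r2=cv_r2,
                       cv_mae=cv_mae, fold_r2=fold_r2)


def predict_sigma_v(
    model: SigmaVModel,
    records: Sequence[HalfHourRecord],
    meta: SiteMeta,
) -> list[HalfHourRecord]:
    """Fill missing σ_v from the model; measured values are never touched."""
    rows = []
    idx = []
    for i, rec in enumerate(records):
        if rec.sigma_v is not None and np.isfinite(rec.sigma_v):
            continue
        z0, _ = meta.roughness_at(rec.timestamp)
        rows.append({
            "USTAR": rec.ustar, "WS": rec.ws, "SW_IN": rec.sw_in,
            "PA": rec.pa, "Z0": z0, "HM": meta.zm, "HC": meta.hc_at(rec.timestamp),
        })
        idx.append(i)
    out = list(records)
    if rows:
        preds = model.predict(pd.DataFrame(rows))
        for i, p in zip(idx, preds):
            out[i] = replace(out[i], sigma_v=float(p))
    return out
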