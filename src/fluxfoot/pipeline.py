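"""End-to-end pipeline: met screening → footprints → climatology → overlays.

``run_pipeline`` binds the stages together for one tower: quality-filter
the half-hourly drivers, fill missing σ_v with the fitted predictor,
stream half-hourly footprints into the cumulative climatology, extract the
50/60/70/80 % contours, overlay land cover and NDVI, compute semivariograms
and sensor location bias, and rate the site's representativeness.  All
outputs are CSV tables plus a plain-text manifest; re-running with the same
configuration reproduces them byte for byte.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .climatology import ACFC, ContourSet, accumulate, extract_contours
from .footprint import FootprintGrid, FootprintInvalidError, halfhour_footprint
from .heterogeneity import (
    DIRECTIONS,
    directional_semivariogram,
    fit_spherical,
    omnidirectional,
)
from .io import areas_to_frame, contours_to_frame, read_fluxnet_csv
from .landcover import (
    IGBP_NAMES,
    aggregate_to_igbp,
    resolve_dominant,
    weighted_cover,
)
from .micromet import SiteMeta, fit_sigma_v, predict_sigma_v, qc_filter
from .rasters import GridSpec, read_ascii_grid
from .representativeness import (
    classify_site,
    footprint_weighted_ndvi,
    sensor_location_bias,
    target_mean_ndvi,
    window_profile,
)
from .synthetic import (
    SceneConfig,
    gen_landcover_raster,
    gen_met_series,
    gen_ndvi_field,
    gen_sigma_v_training,
)

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Inputs may be files (``met_csv``, ``landcover_path``, ``ndvi_path`` as
    headered ASCII grids) or, when a path is None, generated from ``scene``.
    """

    outdir: str | Path
    site: SiteMeta
    scene: SceneConfig = field(default_factory=SceneConfig)
    met_csv: str | Path | None = None
    landcover_path: str | Path | None = None
    ndvi_path: str | Path | None = None
    grid_cell: float = 10.0
    grid_half_width: float | None = None    # default: the scene extent
    levels: tuple[int, ...] = (50, 60, 70, 80)
    convective_pblh: float = 2000.0
    sigma_v_training_n: int = 8000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        site = SiteMeta(**raw.pop("site"))
        scene = SceneConfig(**raw.pop("scene", {}))
        if "levels" in raw:
            raw["levels"] = tuple(raw["levels"])
        return cls(site=site, scene=scene, **raw)


@dataclass
class PipelineResult:
    acfc: ACFC
    contours: ContourSet
    cover: object
    variograms: dict[str, object]
    spherical: object
    slb: object
    windows: object
    classification: object
    report: object
    sigma_v_cv_r2: float | None


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full representativeness analysis for one tower."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    site = config.site

    def stage(name):
        log.info("pipeline stage: %s", name)
        return name

    # --- inputs -----------------------------------------------------------
    stage("inputs")
    records = (read_fluxnet_csv(config.met_csv) if config.met_csv
               else gen_met_series(config.scene))
    n_raw = len(records)
    records = [r for r in records if r.is_complete]
    n_incomplete = n_raw - len(records)

    landcover = (read_ascii_grid(config.landcover_path, categorical=True)
                 if config.landcover_path else gen_landcover_raster(config.scene))
    ndvi = (read_ascii_grid(config.ndvi_path)
            if config.ndvi_path else gen_ndvi_field(config.scene))

    # --- micromet ---------------------------------------------------------
    stage("micromet")
    kept, report = qc_filter(records, site, config.convective_pblh)
    if not kept:
        raise RuntimeError("micromet stage: no records survive the validity filter")

    cv_r2 = None
    if any(r.sigma_v is None for r in kept):
        training, _ = gen_sigma_v_training(config.scene, n=config.sigma_v_training_n)
        model = fit_sigma_v(training, folds=5, seed=config.seed)
        cv_r2 = model.cv_r2
        kept = predict_sigma_v(model, kept, site)

    # --- footprints -> climatology ---------------------------------------
    stage("footprint climatology")
    hw = config.grid_half_width or config.scene.raster_extent
    grid = GridSpec(cell_size=config.grid_cell, half_width=hw)

    def stream() -> "FootprintGrid":
        for rec in kept:
            try:
                yield halfhour_footprint(rec, site, grid, config.convective_pblh)
            except FootprintInvalidError:  # pragma: no cover - filtered upstream
                continue

    acfc = accumulate(stream())
    contours = extract_contours(acfc, config.levels)
    mask80 = contours.mask(80)
    w80 = np.where(mask80, acfc.weights, 0.0)

    # --- land cover -------------------------------------------------------
    stage("landcover overlay")
    igbp = aggregate_to_igbp(landcover)
    cover = weighted_cover(w80, mask80, grid, igbp)
    cover = resolve_dominant(cover, site.igbp_code)

    # --- heterogeneity ----------------------------------------------------
    stage("semivariogram")
    ndvi_weights = acfc.resample_weights(ndvi.grid) if ndvi.grid != grid else w80
    ndvi_mask80 = ndvi_weights > 0
    directional = {
        name: directional_semivariogram(ndvi.values, ndvi_mask80, ndvi.grid.cell_size,
                                        name, weights=ndvi_weights)
        for name in DIRECTIONS
    }
    omni = omnidirectional(list(directional.values()))
    spherical = fit_spherical(omni)
    variograms = dict(directional)
    variograms["omni"] = omni

    # --- representativeness ----------------------------------------------
    stage("sensor location bias")
    ndvi_fp = footprint_weighted_ndvi(w80, mask80, grid, ndvi)
    target = target_mean_ndvi(mask80, grid, ndvi)
    slb = sensor_location_bias(ndvi_fp, target)
    windows = window_profile(ndvi, ndvi_fp)
    classification = classify_site(cover.dominant_pct, spherical.nugget_sill_ratio,
                                   slb.abs_slb if slb.abs_slb is not None else np.inf)

    # --- outputs ----------------------------------------------------------
    stage("write outputs")
    contours_to_frame(contours).to_csv(outdir / "acfcc_contours.csv", index=False)
    areas_to_frame(contours).to_csv(outdir / "acfcc_areas.csv", index=False)
    pd.DataFrame([
        {"igbp_code": c, "igbp": IGBP_NAMES.get(c, str(c)), "percent": p}
        for c, p in sorted(cover.percentages.items(), key=lambda kv: -kv[1])
    ]).to_csv(outdir / "cover_percentages.csv", index=False)
    _variogram_frame(variograms, spherical).to_csv(outdir / "semivariogram.csv",
                                                   index=False)
    slb_frame = windows.to_frame()
    slb_frame.insert(0, "site_id", site.site_id)
    contour_row = pd.DataFrame([{
        "site_id": site.site_id, "window_side_m": np.nan,
        "ndvi_target": slb.ndvi_target, "ndvi_fp": slb.ndvi_fp,
        "slb": slb.slb, "abs_slb": slb.abs_slb,
    }])
    pd.concat([contour_row, slb_frame], ignore_index=True).to_csv(
        outdir / "slb.csv", index=False)
    pd.DataFrame([{
        "site_id": site.site_id, "Rp": classification.rp,
        "Rs": classification.rs, "Rb": classification.rb,
        "dominant_igbp": IGBP_NAMES.get(cover.dominant_class, "?"),
        "dominant_pct": cover.dominant_pct,
        "nugget_sill_ratio_pct": spherical.nugget_sill_ratio,
        "abs_slb": slb.abs_slb, "match": cover.match,
        "alias_applied": cover.alias_applied,
    }]).to_csv(outdir / "classification.csv", index=False)
    _write_manifest(outdir / "manifest.txt", config, report, n_raw, n_incomplete,
                    acfc, contours, cv_r2)

    return PipelineResult(acfc=acfc, contours=contours, cover=cover,
                          variograms=variograms, spherical=spherical, slb=slb,
                          windows=windows, classification=classification,
                          report=report, sigma_v_cv_r2=cv_r2)


def _variogram_frame(variograms: dict, spherical) -> pd.DataFrame:
    rows = []
    for name, est in variograms.items():
        fit = fit_spherical(est) if name != "omni" else spherical
        rows.append({
            "direction": name, "nugget": fit.nugget, "sill": fit.sill,
            "range_m": fit.range_m,
            "nugget_sill_ratio_pct": fit.nugget_sill_ratio,
        })
    return pd.DataFrame(rows)


def _write_manifest(path: Path, config: RunConfig, report, n_raw: int,
                    n_incomplete: int, acfc, contours, cv_r2) -> None:
    lines = [
        f"fluxfoot {__version__}",
        f"site {config.site.site_id}",
        f"seed {config.seed}",
        f"records_read {n_raw}",
        f"records_incomplete {n_incomplete}",
        f"qc_input {report.n_input}",
        f"qc_kept {report.n_kept}",
        f"qc_rejected_stability {report.n_rejected_stability}",
        f"qc_rejected_height_low {report.n_rejected_height_low}",
        f"qc_rejected_height_high {report.n_rejected_height_high}",
        f"footprints_accumulated {acfc.n_contributing}",
        f"fetch_m {contours.fetch_m:.2f}",
        f"symmetry_index {contours.si:.4f}",
    ]
    if cv_r2 is not None:
        lines.append(f"sigma_v_cv_r2 {cv_r2:.4f}")
    path.write_text("\n".join(lines) + "\n")
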