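"""Land-cover aggregation and footprint-weighted cover statistics.

Recodes GLC_FCS30-style 30 m land-cover classes to the IGBP scheme used to
label flux sites, overlays the 80 % footprint-climatology mask, and
computes footprint-weighted cover percentages, the dominant type, and
whether it matches the site's IGBP label (with the savanna/shrubland alias
corrections applied, since the fine-classification product has no classes
for WSA/SAV/CSH).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .rasters import CategoricalRaster, GridSpec

log = logging.getLogger(__name__)

__all__ = [
    "GLC_FCS30_TO_IGBP",
    "IGBP_NAMES",
    "IGBP_ALIASES",
    "CoverSummary",
    "aggregate_to_igbp",
    "weighted_cover",
    "resolve_dominant",
]

#: GLC_FCS30 class code -> IGBP class code
GLC_FCS30_TO_IGBP: dict[int, int] = {
    10: 12, 11: 12, 12: 12, 20: 12,          # croplands
    50: 2,                                    # evergreen broadleaf forest
    60: 4, 61: 4, 62: 4,                      # deciduous broadleaf forest
    70: 1, 71: 1, 72: 1,                      # evergreen needleleaf forest
    80: 3, 81: 3, 82: 3,                      # deciduous needleleaf forest
    90: 5,                                    # mixed forest
    120: 7, 121: 7, 122: 7,                   # open shrublands
    130: 10,                                  # grasslands
    140: 16, 150: 16, 152: 16, 153: 16,       # barren / sparse vegetation
    180: 11,                                  # permanent wetlands
    190: 13,                                  # urban and built-up
    200: 16, 201: 16, 202: 16,                # bare areas -> barren
    210: 18,                                  # water bodies
    220: 15,                                  # permanent snow and ice
    250: 17,                                  # filled value -> unclassified
}

IGBP_NAMES: dict[int, str] = {
    1: "ENF", 2: "EBF", 3: "DNF", 4: "DBF", 5: "MF",
    6: "CSH", 7: "OSH", 8: "WSA", 9: "SAV", 10: "GRA",
    11: "WET", 12: "CRO", 13: "URB", 14: "CVM", 15: "SNO",
    16: "BSV", 17: "UNC", 18: "WAT",
}

#: site IGBP -> the class the 30 m product maps that vegetation onto
#: (woody savannas and closed shrublands present as deciduous broadleaf
#: forest, savannas as evergreen needleleaf forest)
IGBP_ALIASES: dict[int, int] = {8: 4, 9: 1, 6: 4}


@dataclass
class CoverSummary:
    """Footprint-weighted cover percentages within the 80 % contour."""

    percentages: dict[int, float]     # IGBP code -> percent of footprint weight
    dominant_class: int
    dominant_pct: float
    match: bool | None = None
    alias_applied: bool = False


def aggregate_to_igbp(
    raster: CategoricalRaster,
    mapping: dict[int, int] | None = None,
) -> CategoricalRaster:
    """Code-for-code recode of a fine-classification raster to IGBP."""
    mapping = GLC_FCS30_TO_IGBP if mapping is None else mapping
    codes = raster.codes
    present = np.unique(codes)
    unmapped = [int(c) for c in present if c != raster.nodata and c not in mapping]
    if unmapped:
        raise ValueError(f"unmapped land-cover codes: {unmapped}")
    out = np.full_like(codes, raster.nodata)
    for src, dst in mapping.items():
        out[codes == src] = dst
    return CategoricalRaster(raster.grid, out, nodata=raster.nodata)


def weighted_cover(
    weights: np.ndarray,
    mask: np.ndarray,
    grid: GridSpec,
    igbp: CategoricalRaster,
) -> CoverSummary:
    """Footprint-weighted percentage of each IGBP class inside the mask.

    ``weights``/``mask`` live on the footprint ``grid``; the class raster is
    sampled at each footprint cell centre by nearest neighbour.  Nodata
    samples (e.g. footprint cells outside the raster) are excluded before
    normalising, so percentages always sum to 100 over the classes present.
    """
    if not np.any(mask):
        raise ValueError("empty footprint mask")
    X, Y = grid.meshgrid()
    codes = igbp.sample(X[mask], Y[mask])
    w = np.asarray(weights, dtype=float)[mask]
    valid = codes != igbp.nodata
    if not np.any(valid):
        raise ValueError("footprint mask does not overlap the land-cover raster")
    codes, w = codes[valid], w[valid]
    total = w.sum()
    pct: dict[int, float] = {}
    for c in np.unique(codes):
        pct[int(c)] = 100.0 * w[codes == c].sum() / total
    # dominant: highest percentage, ties to the smaller IGBP code
    dominant = min(pct, key=lambda c: (-pct[c], c))
    return CoverSummary(percentages=pct, dominant_class=dominant,
                        dominant_pct=pct[dominant])


def resolve_dominant(
    summary: CoverSummary,
    site_igbp: int,
    alias_map: dict[int, int] | None = None,
) -> CoverSummary:
    """Set match/alias flags comparing the dominant class to the site label."""
    alias_map = IGBP_ALIASES if alias_map is None else alias_map
    summary.alias_applied = False
    if summary.dominant_class == site_igbp:
        summary.match = True
    elif alias_map.get(site_igbp) == summary.dominant_class:
        summary.match = True
        summary.alias_applied = True
        log.info("alias correction: site %s matched via dominant %s",
                 IGBP_NAMES.get(site_igbp, site_igbp),
                 IGBP_NAMES.get(summary.dominant_class, summary.dominant_class))
    else:
        summary.match = False
    return summary
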