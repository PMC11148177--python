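"""Readers and writers for the pipeline's plain-text formats.

Half-hourly met tables follow the FLUXNET2015 FULLSET dialect: one row per
averaging interval, ``TIMESTAMP_START`` as YYYYMMDDHHMM, −9999 for missing
values, and column names like WS_F / USTAR / SW_IN_F.  Output tables are
CSV; contour tables use the fp50_x/fp50_y ... fp80_x/fp80_y column layout.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .climatology import ContourSet
from .micromet import HalfHourRecord

__all__ = [
    "DEFAULT_COLUMN_MAP",
    "read_fluxnet_csv",
    "write_fluxnet_csv",
    "contours_to_frame",
    "areas_to_frame",
]

MISSING = -9999.0

#: record field -> acceptable column names, first match wins
DEFAULT_COLUMN_MAP: dict[str, tuple[str, ...]] = {
    "ws": ("WS_F", "WS"),
    "wd": ("WD",),
    "ustar": ("USTAR",),
    "sigma_v": ("V_SIGMA", "SIGMA_V"),
    "L": ("MO_LENGTH", "L"),
    "pblh": ("PBLH",),
    "sw_in": ("SW_IN_F", "SW_IN"),
    "pa": ("PA_F", "PA"),
    "ta": ("TA_F", "TA"),
    "h": ("H_F", "H"),
}

MANDATORY = ("ws", "wd", "ustar", "pa", "ta", "h")


def read_fluxnet_csv(
    path: str | Path,
    column_map: dict[str, tuple[str, ...]] | None = None,
) -> list[HalfHourRecord]:
    """Parse a FLUXNET-style half-hourly CSV into records.

    −9999 becomes missing; records missing a mandatory driver are returned
    with the field set to None (``HalfHourRecord.is_complete`` is False).
    Unknown columns are ignored.  A mandatory driver whose column is absent
    entirely raises a schema error naming it.
    """
    column_map = DEFAULT_COLUMN_MAP if column_map is None else column_map
    df = pd.read_csv(path)
    if "TIMESTAMP_START" not in df.columns:
        raise KeyError("missing mandatory column: TIMESTAMP_START")
    times = pd.to_datetime(df["TIMESTAMP_START"].astype(str).str.slice(0, 12),
                           format="%Y%m%d%H%M")

    resolved: dict[str, str | None] = {}
    for attr, names in column_map.items():
        resolved[attr] = next((c for c in names if c in df.columns), None)
    for attr in MANDATORY:
        if resolved.get(attr) is None:
            raise KeyError(f"missing mandatory column for '{attr}' "
                           f"(tried {column_map[attr]})")

    records = []
    for i in range(len(df)):
        kwargs: dict = {"timestamp": times.iloc[i]}
        for attr, col in resolved.items():
            if col is None:
                continue
            val = df[col].iloc[i]
            kwargs[attr] = None if (pd.isna(val) or val == MISSING) else float(val)
        records.append(HalfHourRecord(**kwargs))
    return records


def write_fluxnet_csv(path: str | Path, records: Sequence[HalfHourRecord]) -> None:
    """Write records in the FULLSET-like dialect (−9999 for missing)."""
    rows = []
    for r in records:
        def m(v):
            return MISSING if v is None or not np.isfinite(v) else v
        rows.append({
            "TIMESTAMP_START": r.timestamp.strftime("%Y%m%d%H%M"),
            "WS_F": m(r.ws), "WD": m(r.wd), "USTAR": m(r.ustar),
            "V_SIGMA": m(r.sigma_v), "MO_LENGTH": m(r.L), "PBLH": m(r.pblh),
            "SW_IN_F": m(r.sw_in), "PA_F": m(r.pa), "TA_F": m(r.ta), "H_F": m(r.h),
        })
    pd.DataFrame(rows).to_csv(path, index=False)


def contours_to_frame(contours: ContourSet) -> pd.DataFrame:
    """Contour polylines as fp50_x/fp50_y ... fp80_x/fp80_y columns (metres).

    Polylines of one level are concatenated (parts separated by a NaN row);
    columns are padded to the longest level with NaN.
    """
    series: dict[str, np.ndarray] = {}
    for level, cl in sorted(contours.levels.items()):
        parts: list[np.ndarray] = []
        for line in cl.polylines:
            if parts:
                parts.append(np.full((1, 2), np.nan))
            parts.append(line)
        xy = np.vstack(parts) if parts else np.empty((0, 2))
        series[f"fp{level}_x"] = xy[:, 0]
        series[f"fp{level}_y"] = xy[:, 1]
    length = max((len(v) for v in series.values()), default=0)
    out = {k: np.concatenate([v, np.full(length - len(v), np.nan)])
           for k, v in series.items()}
    return pd.DataFrame(out)


def areas_to_frame(contours: ContourSet) -> pd.DataFrame:
    """Contour areas in m² and km², one row per level."""
    rows = [{"level_pct": level, "area_m2": cl.area_m2, "area_km2": cl.area_m2 / 1e6}
            for level, cl in sorted(contours.levels.items())]
    return pd.DataFrame(rows)
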