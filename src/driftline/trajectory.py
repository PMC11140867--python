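"""Travel-line construction and tide-corrected depth assignment.

Successive retained fixes are joined into directed line segments carrying
length (Euclidean, projected meters — no great-circle correction is needed
at bay scale), duration, speed, heading (degrees clockwise from grid
north) and signed turn angle wrapped to (-180, 180].  All segment
attributes are assigned to the destination fix ("second-point
attribution"), so a segment row describes the movement that *arrived* at
that fix.

Depth at a fix is the DEM elevation (bilinear) corrected for tide stage:
``depth = -elevation_MSL + water_level(t)``, positive downward.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from shapely.geometry import Point
from shapely.prepared import prep

from .geodesy import heading_deg, wrap_angle_deg
from .telemetry_io import (SAMPLE_OUT_OF_BOUNDS, BathymetryGrid, TideSeries,
                           sample_raster)

GAP_FLAG_HOURS = 4.0  # segments longer than this are flagged for home-range use


def build_segments(fixes: pd.DataFrame, gap_flag_h: float = GAP_FLAG_HOURS
                   ) -> pd.DataFrame:
    """Convert per-turtle fix sequences into attributed travel segments.

    Returns one row per segment with columns ``turtle_id, start_fix_id,
    end_fix_id, timestamp (segment end), end_easting/end_northing, length_m,
    duration_h, speed_kmh, heading_deg, turn_angle_deg (NaN for each
    turtle's first segment), is_gap``.  Duplicate timestamps are rejected.
    """
    if "easting" not in fixes.columns:
        raise ValueError("build_segments requires projected fixes")
    fixes = fixes.sort_values(["turtle_id", "timestamp"], kind="stable")
    parts = []
    for tid, sub in fixes.groupby("turtle_id", sort=False):
        if len(sub) < 2:
            continue
        t = pd.to_datetime(sub["timestamp"], utc=True)
        dt_h = t.diff().dt.total_seconds().to_numpy()[1:] / 3600.0
        if np.any(dt_h <= 0):
            k = int(np.nonzero(dt_h <= 0)[0][0])
            raise ValueError(
                f"duplicate or non-increasing timestamps for turtle {tid}: "
                f"fix ids {sub['fix_id'].iloc[k]} and {sub['fix_id'].iloc[k + 1]}")
        de = np.diff(sub["easting"].to_numpy())
        dn = np.diff(sub["northing"].to_numpy())
        length_m = np.hypot(de, dn)
        heading = heading_deg(de, dn)
        turn = np.full(len(heading), np.nan)
        turn[1:] = wrap_angle_deg(np.diff(heading))
        parts.append(pd.DataFrame({
            "turtle_id": tid,
            "start_fix_id": sub["fix_id"].to_numpy()[:-1],
            "end_fix_id": sub["fix_id"].to_numpy()[1:],
            "timestamp": t.to_numpy()[1:],
            "start_easting": sub["easting"].to_numpy()[:-1],
            "start_northing": sub["northing"].to_numpy()[:-1],
            "end_easting": sub["easting"].to_numpy()[1:],
            "end_northing": sub["northing"].to_numpy()[1:],
            "lon": sub["lon"].to_numpy()[1:],
            "lat": sub["lat"].to_numpy()[1:],
            "water_temp_C": (sub["water_temp_C"].to_numpy()[1:]
                             if "water_temp_C" in sub.columns else np.nan),
            "length_m": length_m,
            "duration_h": dt_h,
            "speed_kmh": (length_m / 1000.0) / dt_h,
            "heading_deg": heading,
            "turn_angle_deg": turn,
            "is_gap": dt_h > gap_flag_h,
        }))
    if not parts:
        return pd.DataFrame(columns=[
            "turtle_id", "start_fix_id", "end_fix_id", "timestamp",
            "start_easting", "start_northing",
            "end_easting", "end_northing", "lon", "lat", "water_temp_C",
            "length_m", "duration_h", "speed_kmh", "heading_deg",
            "turn_angle_deg", "is_gap"])
    return pd.concat(parts, ignore_index=True)


def assign_depth(fixes: pd.DataFrame, bathy: BathymetryGrid, tide: TideSeries,
                 easting_col: str = "easting", northing_col: str = "northing",
                 max_tide_gap_min: float = 30.0) -> pd.DataFrame:
    """Attach tide-corrected water depth (m, positive down) to each record.

    Adds ``depth_m`` and ``depth_flag`` columns; records outside the raster
    or beyond tide coverage get NaN depth with an explanatory flag.
    """
    out = fixes.copy()
    elev, status = sample_raster(bathy, out[easting_col].to_numpy(),
                                 out[northing_col].to_numpy())
    level = tide.level_at(out["timestamp"], max_gap_min=max_tide_gap_min)
    depth = -elev + level
    flag = np.where(status == SAMPLE_OUT_OF_BOUNDS, "out_of_raster", "ok").astype(object)
    flag[np.isnan(level)] = "no_tide_cover"
    depth[flag != "ok"] = np.nan
    out["depth_m"] = depth
    out["depth_flag"] = flag
    return out


def classify_bay(fixes: pd.DataFrame, bay_polygon,
                 easting_col: str = "easting", northing_col: str = "northing"
                 ) -> pd.DataFrame:
    """Point-in-polygon test against the bay outline (boundary counts inside)."""
    if not bay_polygon.is_valid or bay_polygon.is_empty:
        raise ValueError("bay polygon is invalid or empty")
    prepared = prep(bay_polygon)
    out = fixes.copy()
    out["in_bay"] = [
        prepared.intersects(Point(e, n))
        for e, n in zip(out[easting_col].to_numpy(), out[northing_col].to_numpy())
    ]
    return out


def segments_to_wkt(segments: pd.DataFrame, fixes: pd.DataFrame) -> pd.Series:
    """WKT LINESTRING per segment (projected coordinates) for GIS export."""
    pos = fixes.set_index("fix_id")[["easting", "northing"]]
    start = pos.loc[segments["start_fix_id"]].to_numpy()
    end = pos.loc[segments["end_fix_id"]].to_numpy()
    return pd.Series([
        f"LINESTRING ({x0} {y0}, {x1} {y1})"
        for (x0, y0), (x1, y1) in zip(start, end)
    ], index=segments.index, name="wkt")
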