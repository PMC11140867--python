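"""Descriptive movement statistics and per-turtle summary tables.

Travel speeds are summarized per stratum (bay vs. gulf, depth class, diel
class, temperature bin) as the median with an empirical 95% range — the
2.5th to 97.5th percentiles of segment speeds, linear-interpolation
convention, one value per segment.  The temperature effect on speed is a
fixed-effects least-squares slope (speed on temperature with a separate
intercept per turtle), a deliberately descriptive stand-in for a
mixed-model fit: the slope is comparable, the inference machinery is not.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

DEPTH_CUT_M = 6.0


def speed_summary(speeds: np.ndarray, label: str = "") -> dict:
    """Median and empirical 95% range of a speed sample (km/h)."""
    s = np.asarray(speeds, dtype=float)
    s = s[~np.isnan(s)]
    return {
        "stratum": label,
        "n_segments": len(s),
        "median_kmh": float(np.median(s)) if len(s) else np.nan,
        "q2.5_kmh": float(np.percentile(s, 2.5)) if len(s) else np.nan,
        "q97.5_kmh": float(np.percentile(s, 97.5)) if len(s) else np.nan,
    }


def speed_by_stratum(segments: pd.DataFrame, strata: dict[str, pd.Series]
                     ) -> pd.DataFrame:
    """Speed summaries for named boolean strata over the segment table.

    ``strata`` maps a label to a boolean Series aligned with ``segments``;
    empty strata are omitted with a log entry.
    """
    rows = []
    for label, sel in strata.items():
        sub = segments.loc[sel.to_numpy(bool), "speed_kmh"]
        if len(sub) == 0:
            logger.info("speed_by_stratum: stratum %r empty, omitted", label)
            continue
        rows.append(speed_summary(sub.to_numpy(), label))
    return pd.DataFrame(rows)


def standard_strata(segments: pd.DataFrame,
                    depth_cut_m: float = DEPTH_CUT_M) -> dict[str, pd.Series]:
    """The analysis' canonical strata where the needed columns exist."""
    strata: dict[str, pd.Series] = {}
    if "in_bay" in segments.columns:
        strata["bay"] = segments["in_bay"].astype(bool)
        strata["gulf"] = ~segments["in_bay"].astype(bool)
    if "depth_m" in segments.columns:
        inbay = (segments["in_bay"].astype(bool) if "in_bay" in segments.columns
                 else pd.Series(True, index=segments.index))
        strata[f"bay_depth<{depth_cut_m:g}m"] = inbay & (segments["depth_m"] < depth_cut_m)
        strata[f"bay_depth>={depth_cut_m:g}m"] = inbay & (segments["depth_m"] >= depth_cut_m)
    if "diel_base" in segments.columns:
        strata["day"] = segments["diel_base"] == "day"
        strata["night"] = segments["diel_base"] == "night"
    return strata


def temp_speed_slope(segments: pd.DataFrame) -> dict:
    """OLS slope of speed on temperature with per-turtle intercepts.

    Returns ``slope_kmh_per_C``, its standard error, and the 95% CI.
    Requires ≥ 2 turtles and non-degenerate temperatures.
    """
    sub = segments.dropna(subset=["speed_kmh", "water_temp_C"])
    if sub["turtle_id"].nunique() < 2:
        raise ValueError("temperature-speed slope needs at least two turtles")
    dummies = pd.get_dummies(sub["turtle_id"], dtype=float)
    X = pd.concat([sub["water_temp_C"].rename("temp"), dummies], axis=1)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("design matrix is rank deficient "
                         "(constant temperature within turtles?)")
    fit = sm.OLS(sub["speed_kmh"].to_numpy(), X.to_numpy()).fit()
    ci = fit.conf_int()[0]
    return {
        "slope_kmh_per_C": float(fit.params[0]),
        "se": float(fit.bse[0]),
        "ci_low": float(ci[0]),
        "ci_high": float(ci[1]),
        "n_segments": int(fit.nobs),
    }


def table1(fixes: pd.DataFrame, segments: pd.DataFrame,
           homeranges_50: dict, homeranges_90: dict,
           episodes: list) -> pd.DataFrame:
    """Per-turtle summary: locations, days tracked, in-bay count, home-range
    areas, drifting episode count and percent time; plus a column-mean row.

    ``homeranges_*`` map turtle_id to a HomeRange (or None); turtles with
    no fixes are excluded with a log entry.
    """
    from .drifting import drift_summary

    per_drift, _ = drift_summary(episodes, fixes)
    per_drift = per_drift.set_index("turtle_id")
    rows = []
    for tid, sub in fixes.groupby("turtle_id"):
        if len(sub) == 0:
            logger.info("table1: turtle %r has no fixes, excluded", tid)
            continue
        t = pd.to_datetime(sub["timestamp"], utc=True)
        days = int(np.ceil((t.max() - t.min()).total_seconds() / 86400.0))
        hr50 = homeranges_50.get(tid)
        hr90 = homeranges_90.get(tid)
        rows.append({
            "turtle_id": tid,
            "total_locations": len(sub),
            "days_tracked": days,
            "locations_in_bay": int(sub["in_bay"].sum()) if "in_bay" in sub.columns else np.nan,
            "hr50_km2": hr50.area_km2 if hr50 is not None else np.nan,
            "hr90_km2": hr90.area_km2 if hr90 is not None else np.nan,
            "drifting_episodes": int(per_drift.loc[tid, "n_episodes"])
            if tid in per_drift.index else 0,
            "drifting_percent_time": float(per_drift.loc[tid, "percent_time"])
            if tid in per_drift.index else 0.0,
        })
    out = pd.DataFrame(rows)
    if len(out):
        mean_row = out.drop(columns="turtle_id").mean(numeric_only=True)
        mean_row["turtle_id"] = "mean"
        out = pd.concat([out, mean_row.to_frame().T[out.columns]], ignore_index=True)
    return out
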