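"""End-to-end validation experiments on synthetic data.

Each function here builds a synthetic dataset with the generator, runs the
analysis pipeline on it exactly as a user would, and measures how well the
pipeline recovers the generator's known ground truth.  They back both the
acceptance test suite and ``scripts/acceptance.py``.

The solar check uses :func:`almanac_sun_times`, an independent reference
ephemeris coded from the USNO low-precision almanac formulas (solar
position + altitude root-finding) — a different formulation from the NOAA
hour-angle equations used by :mod:`driftline.solar_diel`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import spearmanr

from . import home_range, solar_diel, synthetic_world
from .drifting import detect_drift, drift_summary
from .home_range import isopleth, line_kde
from .qc_filtering import apply_filters
from .solar_diel import annotate_diel
from .synthetic_world import SimConfig, simulate
from .telemetry_io import project_fixes
from .trajectory import assign_depth, build_segments

STUDY_LAT, STUDY_LON = 29.75, -85.35


# --------------------------------------------------------------------------
# independent solar reference (USNO low-precision almanac)

def _almanac_altitude_deg(jd: float, lat: float, lon: float) -> float:
    n = jd - 2451545.0
    L = (280.460 + 0.9856474 * n) % 360.0
    g = np.radians((357.528 + 0.9856003 * n) % 360.0)
    lam = np.radians(L + 1.915 * np.sin(g) + 0.020 * np.sin(2 * g))
    eps = np.radians(23.439 - 0.0000004 * n)
    ra = np.degrees(np.arctan2(np.cos(eps) * np.sin(lam), np.cos(lam))) % 360.0
    dec = np.degrees(np.arcsin(np.sin(eps) * np.sin(lam)))
    gmst = (280.46061837 + 360.98564736629 * n) % 360.0
    ha = np.radians((gmst + lon - ra + 540.0) % 360.0 - 180.0)
    latr, decr = np.radians(lat), np.radians(dec)
    return np.degrees(np.arcsin(np.sin(latr) * np.sin(decr)
                                + np.cos(latr) * np.cos(decr) * np.cos(ha)))


def almanac_sun_times(date, lat: float, lon: float):
    """Sunrise/sunset by root-finding altitude = -0.833° on the almanac."""
    t0 = pd.Timestamp(date).tz_localize("UTC")
    jd0 = t0.timestamp() / 86400.0 + 2440587.5
    noon = jd0 + 0.5 - lon / 360.0
    f = lambda jd: _almanac_altitude_deg(jd, lat, lon) + 0.833
    rise = brentq(f, noon - 0.5, noon, xtol=1e-8)
    sset = brentq(f, noon, noon + 0.5, xtol=1e-8)
    conv = lambda jd: pd.Timestamp((jd - 2440587.5) * 86400.0, unit="s", tz="UTC")
    return conv(rise), conv(sset)


def solar_max_error_minutes(year: int = 2019, lat: float = STUDY_LAT,
                            lon: float = STUDY_LON) -> float:
    """Worst sunrise/sunset disagreement vs. the almanac over a full year."""
    worst = 0.0
    for day in pd.date_range(f"{year}-01-01", periods=365):
        sr, ss = solar_diel.sun_times(day.date(), lat, lon)
        osr, oss = almanac_sun_times(day.date(), lat, lon)
        worst = max(worst, abs((sr - osr).total_seconds()),
                    abs((ss - oss).total_seconds()))
    return worst / 60.0


# --------------------------------------------------------------------------
# kernel density properties

def analytic_isopleth_areas(sigma_m: float = 150.0, cell_size_m: float = 25.0
                            ) -> dict:
    """50/90% areas of a point-like track vs. the Gaussian-disk closed form."""
    seg = pd.DataFrame({"start_easting": [0.0], "start_northing": [0.0],
                        "end_easting": [1.0], "end_northing": [0.0],
                        "length_m": [1.0]})
    surface = line_kde(seg, sigma_m=sigma_m, cell_size_m=cell_size_m)
    out = {}
    for p, mult in ((50, 2 * np.log(2)), (90, 2 * np.log(10))):
        out[f"area{p}_km2"] = isopleth(surface, p).area_km2
        out[f"area{p}_expected_km2"] = np.pi * sigma_m ** 2 * mult / 1e6
    return out


def kde_mass_and_convergence(seed: int, n_segments: int = 1000) -> dict:
    """Mass conservation and grid-convergence on a generator track."""
    cfg = SimConfig(seed=seed, n_turtles=2, start_time="2019-01-01",
                    end_time="2019-02-01")
    world = simulate(cfg)
    fixes = project_fixes(world["fixes"])
    kept, _ = apply_filters(fixes)
    segments = build_segments(kept).head(n_segments)
    areas = {}
    mass_err = 0.0
    for cell in (25.0, 12.5):
        s = line_kde(segments, cell_size_m=cell)
        if cell == 25.0:
            mass_err = abs(s.grid_mass - s.total_mass) / s.total_mass
        areas[cell] = (isopleth(s, 50).area_km2, isopleth(s, 90).area_km2)
    conv = max(abs(areas[12.5][k] - areas[25.0][k]) / areas[25.0][k]
               for k in range(2))
    return {"n_segments": len(segments),
            "mass_error_pct": 100.0 * mass_err,
            "area_change_on_halved_cell_pct": 100.0 * conv}


# --------------------------------------------------------------------------
# filter fixture with enumerable ground truth

def filter_fixture_counts() -> dict:
    """Run the QC pipeline on a hand-enumerable fixture.

    The fixture holds, per construction: 20 hourly base fixes; 3 with HDOP
    above 25; one duplicate chain (3 extra fixes inside 10 min, collapsing
    onto the final fix, which is an original) and one duplicate pair (1
    extra fix); and 2 inserted outliers whose removal re-checks cleanly
    (iterative speed rule).  Expected removals: 3 HDOP, 4 duplicates,
    2 speed; 21 - trailing retained = see returned dict.
    """
    base = pd.Timestamp("2020-06-01", tz="UTC")
    rows = []
    x = 0.0
    for h in range(20):
        hdop = 30.0 if h in (3, 9, 15) else 1.2
        rows.append((base + pd.Timedelta(hours=h), x, hdop))
        x += 50.0
    # duplicate chain before the fix at hour 5 (minutes 52, 55, 58 of hour 4)
    for m in (52, 55, 58):
        rows.append((base + pd.Timedelta(hours=4, minutes=m), 260.0, 1.2))
    # duplicate pair: extra fix 4 min before hour 12
    rows.append((base + pd.Timedelta(hours=11, minutes=56), 598.0, 1.2))
    # two speed outliers between hours 16 and 17 and after hour 18
    rows.append((base + pd.Timedelta(hours=16, minutes=30), 9000.0, 1.2))
    rows.append((base + pd.Timedelta(hours=18, minutes=30), -7000.0, 1.2))

    rows.sort(key=lambda r: r[0])
    from .telemetry_io import unproject
    xs = np.array([r[1] for r in rows])
    ns = np.zeros(len(rows))
    lon, lat = unproject(xs + 654_000.0, ns + 3_290_000.0)
    fixes = pd.DataFrame({
        "fix_id": np.arange(len(rows)), "turtle_id": "T00",
        "timestamp": [r[0] for r in rows],
        "lon": lon, "lat": lat, "hdop": [r[2] for r in rows],
        "water_temp_C": np.nan,
        "easting": xs + 654_000.0, "northing": ns + 3_290_000.0,
    })
    _, report = apply_filters(fixes)
    return report.to_dict()


# --------------------------------------------------------------------------
# drifting recovery

def drift_recovery_experiment(seed: int, n_turtles: int = 10,
                              start: str = "2019-01-01",
                              end: str = "2019-04-01") -> dict:
    """Recover ground-truth drift bouts from the observed, filtered track.

    Detection probabilities 0.7 (day) / 0.9 (night).  A truth bout (>= 14 h)
    counts as recovered when the union of detected episodes overlapping it
    reproduces both of the bout's *observable* boundaries — the first and
    last received fix inside the bout — within 2 h.  The observable extent
    is the right reference for boundary accuracy: when the tag happens to
    miss the first hours of a bout no detector can place the boundary
    earlier than the first fix on this side of the reception gap, and the
    point of the check is the detector, not the radio link.  Episodes
    overlapping no truth bout at all are false episodes.
    """
    cfg = SimConfig(seed=seed, n_turtles=n_turtles, start_time=start,
                    end_time=end, day_detection_prob=0.7,
                    night_detection_prob=0.9)
    world = simulate(cfg)
    fixes = project_fixes(world["fixes"])
    kept, _ = apply_filters(fixes)
    segments = build_segments(kept)
    episodes = detect_drift(segments, kept)

    bouts = world["drift_bouts"]
    long_bouts = bouts[bouts["duration_h"] >= 14.0]
    tol = pd.Timedelta(hours=2)
    kept_t = pd.to_datetime(kept["timestamp"], utc=True)

    recovered = 0
    for b in long_bouts.itertuples():
        ov = [e for e in episodes
              if e.turtle_id == b.turtle_id
              and e.end_time > b.start_time and e.start_time < b.end_time]
        if not ov:
            continue
        in_bout = kept_t[(kept["turtle_id"] == b.turtle_id)
                         & (kept_t >= b.start_time) & (kept_t <= b.end_time)]
        if in_bout.empty:
            continue
        obs_start, obs_end = in_bout.min(), in_bout.max()
        s = min(e.start_time for e in ov)
        en = max(e.end_time for e in ov)
        if abs(s - obs_start) <= tol and abs(en - obs_end) <= tol:
            recovered += 1

    def overlaps_truth(e) -> bool:
        mine = bouts[bouts["turtle_id"] == e.turtle_id]
        return bool(((mine["end_time"] > e.start_time)
                     & (mine["start_time"] < e.end_time)).any())

    n_false = sum(not overlaps_truth(e) for e in episodes)
    return {
        "n_truth_bouts_14h": int(len(long_bouts)),
        "n_episodes": len(episodes),
        "recovery_pct": 100.0 * recovered / len(long_bouts) if len(long_bouts) else np.nan,
        "false_episode_pct": 100.0 * n_false / len(episodes) if episodes else 0.0,
    }


# --------------------------------------------------------------------------
# diel / tide structure recovery

def diel_tide_experiment(seed: int, n_turtles: int = 6,
                         start: str = "2019-01-01",
                         end: str = "2019-03-02") -> dict:
    """Night-vs-day space use and tide-gated shoal occupancy of movers."""
    cfg = SimConfig(seed=seed, n_turtles=n_turtles, start_time=start,
                    end_time=end,
                    archetypes=["diel_mover"] * n_turtles)
    world = simulate(cfg)
    fixes = project_fixes(world["fixes"])
    kept, _ = apply_filters(fixes)
    kept = assign_depth(kept, world["bathymetry"], world["tide"])
    segments = build_segments(kept)
    segments = annotate_diel(segments)

    night_gt_day = 0
    n_pairs = 0
    ratios = []
    for tid, sub in segments.groupby("turtle_id"):
        bounds = (sub["end_easting"].min(), sub["end_northing"].min(),
                  sub["end_easting"].max(), sub["end_northing"].max())
        day = home_range.diel_homerange(sub, "day", 90, bounds=bounds)
        night = home_range.diel_homerange(sub, "night", 90, bounds=bounds)
        if day is None or night is None:
            continue
        n_pairs += 1
        night_gt_day += night.area_km2 > day.area_km2
        ratios.append(night.area_km2 / day.area_km2)

    # nocturnal shoal occupancy vs. tide stage, on the analysis' own depths
    fx = annotate_diel(kept)
    night_fx = fx[(fx["diel_base"] == "night") & fx["depth_m"].notna()]
    on_shoal = (night_fx["depth_m"] < 2.0).astype(float)
    tide_at_fix = synthetic_world.tide_level(cfg, night_fx["timestamp"])
    rho, _ = spearmanr(on_shoal, tide_at_fix)

    return {
        "n_turtles_with_both_ranges": n_pairs,
        "n_night_larger": int(night_gt_day),
        "mean_night_day_area_ratio": float(np.mean(ratios)) if ratios else np.nan,
        "shoal_tide_spearman": float(rho),
    }


# --------------------------------------------------------------------------
# temperature-drift monotonicity

def temperature_drift_experiment(seed: int, n_turtles: int = 6,
                                 start: str = "2019-01-01",
                                 end: str = "2020-01-01") -> dict:
    """Detected drift time-fraction by temperature band over a full year."""
    cfg = SimConfig(seed=seed, n_turtles=n_turtles, start_time=start,
                    end_time=end,
                    archetypes=["deep_resident", "diel_mover"] * (n_turtles // 2))
    world = simulate(cfg)
    fixes = project_fixes(world["fixes"])
    kept, _ = apply_filters(fixes)
    segments = build_segments(kept)
    episodes = detect_drift(segments, kept)
    _, bands = drift_summary(episodes, kept)
    by_band = bands.set_index("band")["drift_fraction"]
    return {
        "drift_fraction_below_16C_pct": 100.0 * by_band["<16C"],
        "drift_fraction_16_28C_pct": 100.0 * by_band["16-28C"],
        "drift_fraction_above_28C_pct": 100.0 * by_band[">28C"],
    }
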