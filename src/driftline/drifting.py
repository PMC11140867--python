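"""Detection and summary of "drifting" episodes.

Drifting is an extended bout of slow, nearly straight, well-received
movement — the signature of a turtle riding surface currents or basking
rather than actively swimming.  A detected episode must satisfy four
criteria: at least 12 h long (episodes beyond 5 days are flagged, not
truncated), segment speeds at or below 0.06 km/h, turning angles under 20°
in magnitude, and GPS reception of at least 50% over the episode's hourly
attempt schedule.

The turning-angle criterion is evaluated on *window-coarsened* headings by
default: the heading of the net displacement over the trailing 2 h is
compared with the heading over the preceding, non-overlapping 2 h window.
At drift speeds the hourly displacement is ~40-60 m, so position error of
a few meters alone produces apparent single-step turns of ±15°; a strict
per-step test therefore measures GPS noise, not behavior.  Coarsening to
2 h windows reduces the angular noise to a few degrees while meandering
(non-drift) movement still decorrelates between adjacent windows and is
rejected.  The strict per-step test and a run-median variant remain
available via ``angle_mode``.

"Continuous" is operationalized with a gap tolerance (default 2 h): since
hourly fixes drop out, qualifying runs separated by at most the tolerance
are merged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

V_DRIFT_KMH = 0.06
ANGLE_MAX_DEG = 20.0
MIN_HOURS = 12.0
MAX_HOURS = 120.0
MIN_RECEPTION = 0.5
GAP_TOL_H = 2.0
ANGLE_WINDOW_H = 2.0


@dataclass
class DriftEpisode:
    turtle_id: str
    start_time: pd.Timestamp
    end_time: pd.Timestamp
    duration_h: float
    n_segments: int
    mean_speed_kmh: float
    max_abs_turn_deg: float
    reception_fraction: float
    mean_depth_m: float
    mean_temp_C: float
    exceeds_max_duration: bool


def _scheduled_attempts(start: pd.Timestamp, end: pd.Timestamp) -> int:
    """Hourly on-the-hour attempts falling inside [start, end]."""
    first = start.ceil("h")
    last = end.floor("h")
    if last < first:
        return 0
    return int((last - first) / pd.Timedelta(hours=1)) + 1


def _windowed_turns(tf: np.ndarray, xf: np.ndarray, yf: np.ndarray,
                    end_idx: np.ndarray, window_h: float) -> np.ndarray:
    """Turn between adjacent non-overlapping displacement windows.

    For each segment (identified by the index of its end fix), the heading
    of the displacement over the trailing ``window_h`` hours is compared
    with the heading over the window immediately before that.  NaN where a
    window cannot be formed (track start) — treated as exempt upstream.
    """
    turns = np.full(len(end_idx), np.nan)
    for s, e in enumerate(end_idx):
        j = np.searchsorted(tf, tf[e] - window_h, side="right") - 1
        j = min(j, e - 1)
        if j < 0:
            continue
        k = np.searchsorted(tf, tf[j] - window_h, side="right") - 1
        k = min(k, j - 1)
        if k < 0:
            continue
        h1 = np.degrees(np.arctan2(xf[e] - xf[j], yf[e] - yf[j]))
        h0 = np.degrees(np.arctan2(xf[j] - xf[k], yf[j] - yf[k]))
        turns[s] = (h1 - h0 + 180.0) % 360.0 - 180.0
    return turns


def detect_drift(segments: pd.DataFrame, fixes: pd.DataFrame,
                 v_drift: float = V_DRIFT_KMH, angle_max: float = ANGLE_MAX_DEG,
                 min_h: float = MIN_HOURS, max_h: float = MAX_HOURS,
                 min_reception: float = MIN_RECEPTION,
                 gap_tol_h: float = GAP_TOL_H,
                 angle_mode: str = "windowed",
                 angle_window_h: float = ANGLE_WINDOW_H) -> list[DriftEpisode]:
    """Scan attributed segments for drifting episodes.

    ``angle_mode``: ``"windowed"`` (default; see module docstring),
    ``"per_step"`` (raw segment-to-segment turn angles, first segment of a
    run exempt), or ``"run_median"`` (runs form on speed alone and qualify
    if their median per-step |turn| is under ``angle_max``).
    """
    if angle_mode not in ("windowed", "per_step", "run_median"):
        raise ValueError(f"unknown angle_mode {angle_mode!r}")
    episodes: list[DriftEpisode] = []
    fixes = fixes.sort_values(["turtle_id", "timestamp"], kind="stable")
    fix_groups = dict(tuple(fixes.groupby("turtle_id", sort=False)))

    for tid, sub in segments.groupby("turtle_id", sort=False):
        sub = sub.sort_values("timestamp").reset_index(drop=True)
        t_end = pd.to_datetime(sub["timestamp"], utc=True)
        t_start = t_end - pd.to_timedelta(sub["duration_h"], unit="h")
        speed_ok = sub["speed_kmh"].to_numpy() <= v_drift

        tf_series = pd.to_datetime(fix_groups[tid]["timestamp"], utc=True)
        turtle_fix_t = tf_series.reset_index(drop=True)

        if angle_mode == "windowed":
            tf = (tf_series.astype("int64").to_numpy() / 3.6e12)  # hours
            xf = fix_groups[tid]["easting"].to_numpy(float)
            yf = fix_groups[tid]["northing"].to_numpy(float)
            fix_pos = pd.Series(np.arange(len(fix_groups[tid])),
                                index=fix_groups[tid]["fix_id"].to_numpy())
            end_idx = fix_pos.loc[sub["end_fix_id"]].to_numpy()
            turn = _windowed_turns(tf, xf, yf, end_idx, angle_window_h)
        else:
            turn = sub["turn_angle_deg"].to_numpy()
        turn_ok = np.isnan(turn) | (np.abs(turn) < angle_max)

        run: list[int] = []

        def _close_run() -> None:
            if not run:
                return
            rows = sub.iloc[run]
            start = t_start.iloc[run[0]]
            end = t_end.iloc[run[-1]]
            duration_h = (end - start).total_seconds() / 3600.0
            if duration_h < min_h:
                return
            if angle_mode == "run_median":
                per_step = np.abs(rows["turn_angle_deg"].to_numpy())
                per_step = per_step[~np.isnan(per_step)]
                if len(per_step) and np.median(per_step) >= angle_max:
                    return
            n_attempts = _scheduled_attempts(start, end)
            n_received = int(((turtle_fix_t >= start) & (turtle_fix_t <= end)).sum())
            reception = n_received / n_attempts if n_attempts else 0.0
            if reception < min_reception:
                return
            turns_all = np.abs(turn[np.asarray(run)])
            depth = rows["depth_m"].mean() if "depth_m" in rows.columns else np.nan
            temp = (rows["water_temp_C"].mean() if "water_temp_C" in rows.columns
                    else np.nan)
            episodes.append(DriftEpisode(
                turtle_id=str(tid), start_time=start, end_time=end,
                duration_h=duration_h, n_segments=len(rows),
                mean_speed_kmh=float(rows["length_m"].sum() / 1000.0 / duration_h),
                max_abs_turn_deg=(float(np.nanmax(turns_all))
                                  if np.any(~np.isnan(turns_all)) else np.nan),
                reception_fraction=float(reception),
                mean_depth_m=float(depth) if pd.notna(depth) else np.nan,
                mean_temp_C=float(temp) if pd.notna(temp) else np.nan,
                exceeds_max_duration=duration_h > max_h,
            ))

        for i in range(len(sub)):
            in_run = bool(run)
            qualifies = speed_ok[i] and (
                not in_run                      # run seed: no angle requirement
                or angle_mode == "run_median"
                or turn_ok[i]
            )
            if qualifies:
                if in_run:
                    gap_h = (t_start.iloc[i] - t_end.iloc[run[-1]]).total_seconds() / 3600.0
                    if gap_h > gap_tol_h:
                        _close_run()
                        run = []
                run.append(i)
            elif in_run:
                # a non-qualifying stretch may still be bridged if a later
                # qualifying segment starts within gap_tol of the run's end
                gap_h = (t_end.iloc[i] - t_end.iloc[run[-1]]).total_seconds() / 3600.0
                if gap_h > gap_tol_h:
                    _close_run()
                    run = []
        _close_run()
    return episodes


def episodes_frame(episodes: list[DriftEpisode]) -> pd.DataFrame:
    """Episodes as a flat table (empty with full schema when none)."""
    cols = ["turtle_id", "start_time", "end_time", "duration_h", "n_segments",
            "mean_speed_kmh", "max_abs_turn_deg", "reception_fraction",
            "mean_depth_m", "mean_temp_C", "exceeds_max_duration"]
    if not episodes:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame([vars(ep) for ep in episodes])[cols]


def drift_summary(episodes: list[DriftEpisode], fixes: pd.DataFrame,
                  temp_bands: tuple[float, float] = (16.0, 28.0)
                  ) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Per-turtle drifting counts/percent-time and a temperature-band table.

    Percent time = summed episode duration over the turtle's tracked span
    (first to last fix).  The band table gives, for fixes below/between/
    above the band cutpoints (°C), the fraction of time spent drifting,
    approximated by the fraction of hourly fixes inside an episode;
    it is None when no fix temperatures are available.
    """
    t = pd.to_datetime(fixes["timestamp"], utc=True)
    eps = episodes_frame(episodes)

    rows = []
    for tid, sub_t in t.groupby(fixes["turtle_id"]):
        span_h = (sub_t.max() - sub_t.min()).total_seconds() / 3600.0
        mine = eps[eps["turtle_id"] == str(tid)]
        total_h = float(mine["duration_h"].sum())
        rows.append({"turtle_id": tid, "n_episodes": len(mine),
                     "drift_hours": total_h, "tracked_hours": span_h,
                     "percent_time": 100.0 * total_h / span_h if span_h else 0.0})
    per_turtle = pd.DataFrame(rows)

    if "water_temp_C" not in fixes.columns or fixes["water_temp_C"].notna().sum() == 0:
        return per_turtle, None

    in_episode = np.zeros(len(fixes), dtype=bool)
    for ep in episodes:
        in_episode |= ((fixes["turtle_id"].to_numpy() == ep.turtle_id)
                       & (t >= ep.start_time).to_numpy()
                       & (t <= ep.end_time).to_numpy())
    temp = fixes["water_temp_C"].to_numpy(float)
    lo, hi = temp_bands
    band_rows = []
    for label, sel in (
        (f"<{lo:g}C", temp < lo),
        (f"{lo:g}-{hi:g}C", (temp >= lo) & (temp <= hi)),
        (f">{hi:g}C", temp > hi),
    ):
        sel &= ~np.isnan(temp)
        n = int(sel.sum())
        band_rows.append({
            "band": label, "n_fixes": n,
            "drift_fraction": float(in_episode[sel].mean()) if n else np.nan,
        })
    return per_turtle, pd.DataFrame(band_rows)
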