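"""Fix-level quality control for hourly GPS telemetry.

Three filters are applied as a fixed pipeline — HDOP, duplicates, speed —
with exact bookkeeping of removals per turtle:

1. HDOP: fixes with horizontal dilution of precision strictly greater than
   25 are discarded (missing HDOP is retained but counted).
2. Duplicates: when two fixes from one tag arrive within 10 minutes the
   first of the pair is discarded (the later fix is the updated,
   higher-quality solution); a left-to-right scan collapses chains of
   near-simultaneous fixes to the final one.
3. Speed: fixes whose incoming travel speed from the previous retained fix
   exceeds 4 km/h are removed; by default removal iterates until no
   adjacent pair implies more than 4 km/h, since deleting one spurious fix
   changes its successor's incoming speed.  A single-pass mode is kept for
   sensitivity analysis.

Duplicate removal precedes the speed filter deliberately: near-zero time
differences otherwise inflate apparent speeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

HDOP_MAX_DEFAULT = 25.0
DUPLICATE_WINDOW_MIN_DEFAULT = 10.0
SPEED_MAX_KMH_DEFAULT = 4.0


@dataclass
class FilterReport:
    """Count bookkeeping for the QC pipeline; conserves totals exactly."""

    n_input: int = 0
    n_hdop_removed: int = 0
    n_duplicate_removed: int = 0
    n_speed_removed: int = 0
    n_retained: int = 0
    per_turtle: pd.DataFrame = field(default_factory=pd.DataFrame)

    def validate(self) -> None:
        total = (self.n_retained + self.n_hdop_removed
                 + self.n_duplicate_removed + self.n_speed_removed)
        if total != self.n_input:
            raise AssertionError(
                f"count conservation violated: {total} != {self.n_input}")

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_hdop_removed": self.n_hdop_removed,
            "n_duplicate_removed": self.n_duplicate_removed,
            "n_speed_removed": self.n_speed_removed,
            "n_retained": self.n_retained,
        }


def _sorted(fixes: pd.DataFrame) -> pd.DataFrame:
    return fixes.sort_values(["turtle_id", "timestamp"], kind="stable").reset_index(drop=True)


def filter_hdop(fixes: pd.DataFrame, threshold: float = HDOP_MAX_DEFAULT
                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove fixes with HDOP strictly above ``threshold``; keep missing HDOP."""
    hdop = fixes["hdop"]
    bad = hdop.notna() & (hdop > threshold)
    return (fixes.loc[~bad].reset_index(drop=True),
            fixes.loc[bad].reset_index(drop=True))


def filter_duplicates(fixes: pd.DataFrame,
                      window_min: float = DUPLICATE_WINDOW_MIN_DEFAULT
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop the earlier fix of any per-turtle pair closer than ``window_min``.

    Left-to-right scan: whenever the gap to the next fix is under the
    window the current fix is dropped, so a chain of near-simultaneous
    fixes keeps only its last member.
    """
    fixes = _sorted(fixes)
    t = pd.to_datetime(fixes["timestamp"], utc=True).astype("int64").to_numpy() / 1e9
    same_turtle = fixes["turtle_id"].to_numpy()[1:] == fixes["turtle_id"].to_numpy()[:-1]
    gap_s = t[1:] - t[:-1]
    drop = np.zeros(len(fixes), dtype=bool)
    drop[:-1] = same_turtle & (gap_s < window_min * 60.0)
    return (fixes.loc[~drop].reset_index(drop=True),
            fixes.loc[drop].reset_index(drop=True))


def _incoming_speeds_kmh(sub: pd.DataFrame) -> np.ndarray:
    """Speed (km/h) into each fix from its predecessor; NaN for the first."""
    e = sub["easting"].to_numpy()
    n = sub["northing"].to_numpy()
    t = pd.to_datetime(sub["timestamp"], utc=True).astype("int64").to_numpy() / 1e9
    out = np.full(len(sub), np.nan)
    if len(sub) > 1:
        dist_km = np.hypot(np.diff(e), np.diff(n)) / 1000.0
        dt_h = np.diff(t) / 3600.0
        out[1:] = dist_km / dt_h
    return out


def filter_speed(fixes: pd.DataFrame, vmax_kmh: float = SPEED_MAX_KMH_DEFAULT,
                 iterative: bool = True) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove fixes whose incoming speed exceeds ``vmax_kmh``.

    Requires projected coordinates and prior duplicate removal.  In
    iterative mode, speeds are recomputed after each sweep until no
    adjacent retained pair implies more than ``vmax_kmh``.
    """
    if "easting" not in fixes.columns:
        raise ValueError("speed filter requires projected easting/northing")
    fixes = _sorted(fixes)
    if not iterative:
        speeds = np.concatenate([
            _incoming_speeds_kmh(sub)
            for _, sub in fixes.groupby("turtle_id", sort=False)
        ]) if len(fixes) else np.array([])
        bad = np.nan_to_num(speeds, nan=0.0) > vmax_kmh
        return (fixes.loc[~bad].reset_index(drop=True),
                fixes.loc[bad].reset_index(drop=True))

    # iterative rule: each fix is tested against the last *retained* fix, so
    # removing an outlier re-exposes its successor to a fair speed check
    # (equivalent to remove-first-offender-and-recompute until stable)
    drop = np.zeros(len(fixes), dtype=bool)
    e = fixes["easting"].to_numpy()
    n = fixes["northing"].to_numpy()
    t = pd.to_datetime(fixes["timestamp"], utc=True).astype("int64").to_numpy() / 1e9
    for _, idx in fixes.groupby("turtle_id", sort=False).indices.items():
        last = idx[0]
        for i in idx[1:]:
            d_km = np.hypot(e[i] - e[last], n[i] - n[last]) / 1000.0
            dt_h = (t[i] - t[last]) / 3600.0
            if d_km / dt_h > vmax_kmh:
                drop[i] = True
            else:
                last = i
    return (fixes.loc[~drop].reset_index(drop=True),
            fixes.loc[drop].reset_index(drop=True))


def apply_filters(fixes: pd.DataFrame, hdop_max: float = HDOP_MAX_DEFAULT,
                  dup_window_min: float = DUPLICATE_WINDOW_MIN_DEFAULT,
                  vmax_kmh: float = SPEED_MAX_KMH_DEFAULT,
                  iterative_speed: bool = True
                  ) -> tuple[pd.DataFrame, FilterReport]:
    """Run HDOP → duplicate → speed filtering and report exact counts."""
    fixes = _sorted(fixes)
    kept1, rm_hdop = filter_hdop(fixes, hdop_max)
    kept2, rm_dup = filter_duplicates(kept1, dup_window_min)
    kept3, rm_speed = filter_speed(kept2, vmax_kmh, iterative=iterative_speed)

    per = []
    for tid in fixes["turtle_id"].unique():
        per.append({
            "turtle_id": tid,
            "n_input": int((fixes["turtle_id"] == tid).sum()),
            "n_hdop_removed": int((rm_hdop["turtle_id"] == tid).sum()),
            "n_duplicate_removed": int((rm_dup["turtle_id"] == tid).sum()),
            "n_speed_removed": int((rm_speed["turtle_id"] == tid).sum()),
            "n_retained": int((kept3["turtle_id"] == tid).sum()),
        })
    report = FilterReport(
        n_input=len(fixes), n_hdop_removed=len(rm_hdop),
        n_duplicate_removed=len(rm_dup), n_speed_removed=len(rm_speed),
        n_retained=len(kept3), per_turtle=pd.DataFrame(per),
    )
    report.validate()
    return kept3, report


def reception_rates(fixes: pd.DataFrame, attempts_per_day: int = 24
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Daily and hour-of-day GPS success fractions per turtle.

    Daily fraction = fixes that day / 24 scheduled attempts; hour-of-day
    fraction = fixes received in that clock hour / days of tag operation
    (first to last fix, inclusive).
    """
    t = pd.to_datetime(fixes["timestamp"], utc=True)
    df = fixes.assign(_date=t.dt.date, _hour=t.dt.hour)

    daily = (df.groupby(["turtle_id", "_date"]).size() / attempts_per_day) \
        .rename("success_fraction").reset_index().rename(columns={"_date": "date"})

    rows = []
    for tid, sub in df.groupby("turtle_id"):
        days = (sub["_date"].max() - sub["_date"].min()).days + 1
        counts = sub.groupby("_hour").size()
        for hour in range(24):
            rows.append({"turtle_id": tid, "hour_utc": hour,
                         "success_fraction": counts.get(hour, 0) / days})
    return daily, pd.DataFrame(rows)
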