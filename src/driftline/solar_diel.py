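"""Sunrise/sunset computation and diel classification of telemetry records.

Solar event times come from the NOAA solar-position equations (the algorithm
behind the NOAA Solar Calculator): geometric mean solar longitude and
anomaly, equation of center, apparent longitude with nutation correction,
obliquity, declination and equation of time, then the hour angle for a
zenith of 90.833° (refraction plus the solar half-diameter).  Event times
are refined once by re-evaluating the solar position at the first-guess
event time, which brings the result within a few seconds of a full
ephemeris at mid-latitudes.

Diel classes follow the two-layer convention used in the analysis: a base
day/night split at sunrise/sunset, plus a crepuscular overlay covering the
closed ±2 h windows around each event, so that both the 2-way and the 3-way
partitions of the day are available downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date as _date

import numpy as np
import pandas as pd

ZENITH_OFFICIAL_DEG = 90.833  # standard refraction + solar radius

DAY = "day"
NIGHT = "night"
CREPUSCULAR_DAWN = "crepuscular_dawn"
CREPUSCULAR_DUSK = "crepuscular_dusk"


class PolarDayNightError(ValueError):
    """The sun does not cross the horizon on this date at this latitude."""


@dataclass(frozen=True)
class DielWindow:
    """Solar day context: sunrise/sunset (UTC) for one date at one place."""

    date: _date
    sunrise_utc: pd.Timestamp
    sunset_utc: pd.Timestamp
    latitude: float
    longitude: float

    @property
    def daylength_h(self) -> float:
        return (self.sunset_utc - self.sunrise_utc).total_seconds() / 3600.0


def _julian_day(ts: pd.Timestamp) -> float:
    # days since the J2000.0 epoch, from the POSIX timestamp
    return ts.timestamp() / 86400.0 + 2440587.5


def _solar_coords(jd: float) -> tuple[float, float]:
    """Solar declination (deg) and equation of time (minutes) at a Julian day."""
    T = (jd - 2451545.0) / 36525.0
    L0 = (280.46646 + T * (36000.76983 + 0.0003032 * T)) % 360.0
    M = 357.52911 + T * (35999.05029 - 0.0001537 * T)
    ecc = 0.016708634 - T * (0.000042037 + 0.0000001267 * T)
    Mr = np.radians(M)
    C = (np.sin(Mr) * (1.914602 - T * (0.004817 + 0.000014 * T))
         + np.sin(2 * Mr) * (0.019993 - 0.000101 * T)
         + np.sin(3 * Mr) * 0.000289)
    true_long = L0 + C
    omega = np.radians(125.04 - 1934.136 * T)
    app_long = true_long - 0.00569 - 0.00478 * np.sin(omega)
    eps0 = 23.0 + (26.0 + (21.448 - T * (46.815 + T * (0.00059 - 0.001813 * T))) / 60.0) / 60.0
    eps = np.radians(eps0 + 0.00256 * np.cos(omega))
    lam = np.radians(app_long)
    decl = np.degrees(np.arcsin(np.sin(eps) * np.sin(lam)))
    y = np.tan(eps / 2.0) ** 2
    L0r = np.radians(L0)
    eqtime = 4.0 * np.degrees(
        y * np.sin(2 * L0r) - 2 * ecc * np.sin(Mr)
        + 4 * ecc * y * np.sin(Mr) * np.cos(2 * L0r)
        - 0.5 * y * y * np.sin(4 * L0r) - 1.25 * ecc * ecc * np.sin(2 * Mr)
    )
    return float(decl), float(eqtime)


def _hour_angle_deg(lat: float, decl: float, zenith: float) -> float:
    latr, declr = np.radians(lat), np.radians(decl)
    cos_ha = (np.cos(np.radians(zenith)) / (np.cos(latr) * np.cos(declr))
              - np.tan(latr) * np.tan(declr))
    if not -1.0 <= cos_ha <= 1.0:
        raise PolarDayNightError(
            f"no sunrise/sunset at latitude {lat:.3f}° (polar day or night)"
        )
    return float(np.degrees(np.arccos(cos_ha)))


def sun_times(date, lat: float, lon: float,
              zenith_deg: float = ZENITH_OFFICIAL_DEG) -> tuple[pd.Timestamp, pd.Timestamp]:
    """Sunrise and sunset (UTC) for a calendar date at a WGS84 position.

    `date` is the UTC calendar date (datetime.date or anything pandas can
    parse).  Raises :class:`PolarDayNightError` when the sun stays above or
    below the chosen zenith all day.
    """
    if abs(lat) >= 66.0:
        raise PolarDayNightError("latitudes poleward of 66° are unsupported")
    day0 = pd.Timestamp(date).tz_localize("UTC") if pd.Timestamp(date).tz is None \
        else pd.Timestamp(date).tz_convert("UTC")
    day0 = day0.normalize()

    def _event(rise: bool) -> pd.Timestamp:
        # first pass at nominal local solar noon, then refine at the estimate
        t = day0 + pd.Timedelta(hours=12.0 - lon / 15.0)
        for _ in range(2):
            decl, eqtime = _solar_coords(_julian_day(t))
            ha = _hour_angle_deg(lat, decl, zenith_deg)
            noon_min = 720.0 - 4.0 * lon - eqtime
            minutes = noon_min - 4.0 * ha if rise else noon_min + 4.0 * ha
            t = day0 + pd.Timedelta(minutes=minutes)
        return t

    return _event(True), _event(False)


def diel_window(date, lat: float, lon: float) -> DielWindow:
    sr, ss = sun_times(date, lat, lon)
    return DielWindow(date=pd.Timestamp(date).date(), sunrise_utc=sr,
                      sunset_utc=ss, latitude=lat, longitude=lon)


def classify_diel(timestamp, window: DielWindow,
                  crepuscular_h: float = 2.0) -> tuple[str, str]:
    """Classify a UTC timestamp as (base, label).

    base is ``day`` or ``night`` from the sunrise/sunset split (day spans
    [sunrise, sunset)); label additionally marks the closed ±`crepuscular_h`
    windows around sunrise (``crepuscular_dawn``) and sunset
    (``crepuscular_dusk``), and equals base outside them.
    """
    t = pd.Timestamp(timestamp)
    t = t.tz_localize("UTC") if t.tz is None else t.tz_convert("UTC")
    base = DAY if window.sunrise_utc <= t < window.sunset_utc else NIGHT
    tol = pd.Timedelta(hours=crepuscular_h)
    if abs(t - window.sunrise_utc) <= tol:
        return base, CREPUSCULAR_DAWN
    if abs(t - window.sunset_utc) <= tol:
        return base, CREPUSCULAR_DUSK
    return base, base


def annotate_diel(fixes: pd.DataFrame, crepuscular_h: float = 2.0,
                  time_col: str = "timestamp") -> pd.DataFrame:
    """Add ``diel_base`` and ``diel_label`` columns to a fix or segment table.

    The solar window for each turtle-day uses that day's mean fix position
    (tracks move < 0.2° per day here, so event-time sensitivity is < 1 min).
    Requires ``turtle_id``, ``lon``, ``lat`` and a UTC time column.
    """
    out = fixes.copy()
    t = pd.to_datetime(out[time_col], utc=True)
    out["_date"] = t.dt.date
    base = np.empty(len(out), dtype=object)
    label = np.empty(len(out), dtype=object)
    for (_, day), idx in out.groupby(["turtle_id", "_date"]).indices.items():
        sub = out.iloc[idx]
        win = diel_window(day, float(sub["lat"].mean()), float(sub["lon"].mean()))
        for i, ts in zip(idx, t.iloc[idx]):
            base[i], label[i] = classify_diel(ts, win, crepuscular_h)
    out["diel_base"] = base
    out["diel_label"] = label
    return out.drop(columns="_date")
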