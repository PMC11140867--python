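"""Independent reference implementations used only to check the package.

Each oracle is deliberately coded from a different published formulation
than the implementation it checks: Snyder's series for the transverse
Mercator (vs. the Krüger series in the package), the USNO low-precision
almanac solar position with altitude root-finding (vs. the NOAA
hour-angle equations), and plain brute-force scans for the filters and
spatial predicates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import brentq

_A = 6_378_137.0
_F = 1.0 / 298.257_223_563
_E2 = _F * (2.0 - _F)
_EP2 = _E2 / (1.0 - _E2)
_K0 = 0.9996


def snyder_tm_forward(lon_deg: float, lat_deg: float, lon0_deg: float
                      ) -> tuple[float, float]:
    """Transverse Mercator forward per Snyder (1987) eq. 8-9..8-13."""
    phi = np.radians(lat_deg)
    lam = np.radians(lon_deg - lon0_deg)
    N = _A / np.sqrt(1.0 - _E2 * np.sin(phi) ** 2)
    T = np.tan(phi) ** 2
    C = _EP2 * np.cos(phi) ** 2
    Aa = lam * np.cos(phi)
    e2, e4, e6 = _E2, _E2 ** 2, _E2 ** 3
    M = _A * ((1 - e2 / 4 - 3 * e4 / 64 - 5 * e6 / 256) * phi
              - (3 * e2 / 8 + 3 * e4 / 32 + 45 * e6 / 1024) * np.sin(2 * phi)
              + (15 * e4 / 256 + 45 * e6 / 1024) * np.sin(4 * phi)
              - (35 * e6 / 3072) * np.sin(6 * phi))
    x = _K0 * N * (Aa + (1 - T + C) * Aa ** 3 / 6
                   + (5 - 18 * T + T ** 2 + 72 * C - 58 * _EP2) * Aa ** 5 / 120)
    y = _K0 * (M + N * np.tan(phi) * (
        Aa ** 2 / 2 + (5 - T + 9 * C + 4 * C ** 2) * Aa ** 4 / 24
        + (61 - 58 * T + T ** 2 + 600 * C - 330 * _EP2) * Aa ** 6 / 720))
    return x + 500_000.0, y


def almanac_sun_altitude_deg(jd: float, lat: float, lon: float) -> float:
    """Solar altitude from the USNO low-precision almanac formulas."""
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
    return np.degrees(np.arcsin(
        np.sin(latr) * np.sin(decr) + np.cos(latr) * np.cos(decr) * np.cos(ha)))


def almanac_sun_times(date, lat: float, lon: float
                      ) -> tuple[pd.Timestamp, pd.Timestamp]:
    """Sunrise/sunset by root-finding altitude = -0.833° on the almanac."""
    t0 = pd.Timestamp(date).tz_localize("UTC")
    jd0 = t0.timestamp() / 86400.0 + 2440587.5
    noon = jd0 + 0.5 - lon / 360.0

    def f(jd):
        return almanac_sun_altitude_deg(jd, lat, lon) + 0.833

    rise = brentq(f, noon - 0.5, noon, xtol=1e-8)
    sset = brentq(f, noon, noon + 0.5, xtol=1e-8)

    def conv(jd):
        return pd.Timestamp((jd - 2440587.5) * 86400.0, unit="s", tz="UTC")

    return conv(rise), conv(sset)


def bilinear_reference(grid, e: float, n: float) -> float:
    """Textbook bilinear interpolation of the four surrounding cell centers."""
    cs = grid.cell_size
    fx = (e - grid.origin_easting) / cs - 0.5
    fy = (n - grid.origin_northing) / cs - 0.5
    x0 = int(np.clip(np.floor(fx), 0, grid.n_cols - 2))
    y0 = int(np.clip(np.floor(fy), 0, grid.n_rows - 2))
    tx = np.clip(fx - x0, 0.0, 1.0)
    ty = np.clip(fy - y0, 0.0, 1.0)
    z = grid.elevation
    return ((1 - tx) * (1 - ty) * z[y0, x0] + tx * (1 - ty) * z[y0, x0 + 1]
            + (1 - tx) * ty * z[y0 + 1, x0] + tx * ty * z[y0 + 1, x0 + 1])


def ray_casting_inside(poly_xy: np.ndarray, px: float, py: float) -> bool:
    """Even-odd rule point-in-polygon with on-edge counting as inside."""
    n = len(poly_xy)
    inside = False
    for i in range(n):
        x1, y1 = poly_xy[i]
        x2, y2 = poly_xy[(i + 1) % n]
        # on-edge check
        cross = (px - x1) * (y2 - y1) - (py - y1) * (x2 - x1)
        if (abs(cross) < 1e-9
                and min(x1, x2) - 1e-9 <= px <= max(x1, x2) + 1e-9
                and min(y1, y2) - 1e-9 <= py <= max(y1, y2) + 1e-9):
            return True
        if (y1 > py) != (y2 > py):
            xin = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            if px < xin:
                inside = not inside
    return inside


def duplicate_scan_reference(times_min: list[float], window_min: float = 10.0
                             ) -> list[int]:
    """Indices kept by the pairwise 'drop the earlier of any close pair'
    rule, applied left to right until stable."""
    kept = sorted(range(len(times_min)), key=lambda i: times_min[i])
    changed = True
    while changed:
        changed = False
        for a in range(len(kept) - 1):
            if times_min[kept[a + 1]] - times_min[kept[a]] < window_min:
                kept.pop(a)
                changed = True
                break
    return kept


def speed_filter_reference(t_h: np.ndarray, x: np.ndarray, y: np.ndarray,
                           vmax_kmh: float = 4.0) -> list[int]:
    """Iterative removal of fixes with incoming speed above the limit."""
    idx = list(range(len(t_h)))
    while True:
        bad = None
        for a in range(1, len(idx)):
            i0, i1 = idx[a - 1], idx[a]
            d_km = np.hypot(x[i1] - x[i0], y[i1] - y[i0]) / 1000.0
            if d_km / (t_h[i1] - t_h[i0]) > vmax_kmh:
                bad = a
                break
        if bad is None:
            return idx
        idx.pop(bad)


def percentile_reference(values: np.ndarray, q: float) -> float:
    """Sort-based linear-interpolation percentile (numpy 'linear' rule)."""
    s = np.sort(np.asarray(values, float))
    pos = (len(s) - 1) * q / 100.0
    lo = int(np.floor(pos))
    hi = int(np.ceil(pos))
    return s[lo] + (pos - lo) * (s[hi] - s[lo])
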