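"""Transverse Mercator projection on the WGS84 ellipsoid.

Implements the forward and inverse UTM mapping with Krüger's series in the
transverse Mercator conformal coordinates, truncated at n^6 (sub-millimeter
accuracy within a UTM zone and for several degrees beyond its nominal
edges).  The study area (a Gulf of Mexico coastal bay near 29.8°N, 85.3°W)
falls in UTM zone 16N (EPSG:26916 / 32616-style parameters), which is the
default zone throughout the package.

Conventions: eastings/northings in meters, longitudes/latitudes in decimal
degrees; northern hemisphere (false northing 0).
"""

from __future__ import annotations

import numpy as np

# WGS84 defining parameters
WGS84_A = 6_378_137.0
WGS84_F = 1.0 / 298.257_223_563

UTM_K0 = 0.9996
UTM_FALSE_EASTING = 500_000.0

_n = WGS84_F / (2.0 - WGS84_F)

# Rectifying radius: A = a/(1+n) * (1 + n^2/4 + n^4/64 + n^6/256)
_A_RECT = WGS84_A / (1.0 + _n) * (1.0 + _n**2 / 4 + _n**4 / 64 + _n**6 / 256)

# Krüger forward coefficients alpha_j (j = 1..6)
_ALPHA = np.array([
    _n / 2 - 2 * _n**2 / 3 + 5 * _n**3 / 16 + 41 * _n**4 / 180
    - 127 * _n**5 / 288 + 7891 * _n**6 / 37800,
    13 * _n**2 / 48 - 3 * _n**3 / 5 + 557 * _n**4 / 1440
    + 281 * _n**5 / 630 - 1983433 * _n**6 / 1935360,
    61 * _n**3 / 240 - 103 * _n**4 / 140 + 15061 * _n**5 / 26880
    + 167603 * _n**6 / 181440,
    49561 * _n**4 / 161280 - 179 * _n**5 / 168 + 6601661 * _n**6 / 7257600,
    34729 * _n**5 / 80640 - 3418889 * _n**6 / 1995840,
    212378941 * _n**6 / 319334400,
])

# Krüger inverse coefficients beta_j (j = 1..6)
_BETA = np.array([
    _n / 2 - 2 * _n**2 / 3 + 37 * _n**3 / 96 - _n**4 / 360
    - 81 * _n**5 / 512 + 96199 * _n**6 / 604800,
    _n**2 / 48 + _n**3 / 15 - 437 * _n**4 / 1440 + 46 * _n**5 / 105
    - 1118711 * _n**6 / 3870720,
    17 * _n**3 / 480 - 37 * _n**4 / 840 - 209 * _n**5 / 4480
    + 5569 * _n**6 / 90720,
    4397 * _n**4 / 161280 - 11 * _n**5 / 504 - 830251 * _n**6 / 7257600,
    4583 * _n**5 / 161280 - 108847 * _n**6 / 3991680,
    20648693 * _n**6 / 638668800,
])

_E = np.sqrt(WGS84_F * (2.0 - WGS84_F))  # first eccentricity
_J = np.arange(1, 7)


def utm_zone_central_meridian(zone: int) -> float:
    """Central meridian (degrees east) of a UTM zone number."""
    if not 1 <= zone <= 60:
        raise ValueError(f"UTM zone must be in 1..60, got {zone}")
    return -183.0 + 6.0 * zone


def geographic_to_utm(lon, lat, zone: int = 16):
    """Project WGS84 lon/lat (degrees) to UTM easting/northing (m).

    Accepts scalars or arrays; returns a pair of ndarrays (or floats for
    scalar input).  Northern-hemisphere convention (no false northing).
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if np.any(np.abs(lat) > 84.0):
        raise ValueError("latitude outside the UTM domain (|lat| > 84°)")
    lam = np.radians(lon - utm_zone_central_meridian(zone))
    phi = np.radians(lat)

    # conformal latitude
    tau = np.tan(phi)
    sigma = np.sinh(_E * np.arctanh(_E * tau / np.sqrt(1.0 + tau**2)))
    taup = tau * np.sqrt(1.0 + sigma**2) - sigma * np.sqrt(1.0 + tau**2)

    xip = np.arctan2(taup, np.cos(lam))
    etap = np.arcsinh(np.sin(lam) / np.hypot(taup, np.cos(lam)))

    j = _J.reshape((-1,) + (1,) * xip.ndim)
    a = _ALPHA.reshape((-1,) + (1,) * xip.ndim)
    xi = xip + np.sum(a * np.sin(2 * j * xip) * np.cosh(2 * j * etap), axis=0)
    eta = etap + np.sum(a * np.cos(2 * j * xip) * np.sinh(2 * j * etap), axis=0)

    easting = UTM_FALSE_EASTING + UTM_K0 * _A_RECT * eta
    northing = UTM_K0 * _A_RECT * xi
    if easting.ndim == 0:
        return float(easting), float(northing)
    return easting, northing


def utm_to_geographic(easting, northing, zone: int = 16):
    """Inverse UTM: easting/northing (m) to WGS84 lon/lat (degrees)."""
    easting = np.asarray(easting, dtype=float)
    northing = np.asarray(northing, dtype=float)
    xi = northing / (UTM_K0 * _A_RECT)
    eta = (easting - UTM_FALSE_EASTING) / (UTM_K0 * _A_RECT)

    j = _J.reshape((-1,) + (1,) * xi.ndim)
    b = _BETA.reshape((-1,) + (1,) * xi.ndim)
    xip = xi - np.sum(b * np.sin(2 * j * xi) * np.cosh(2 * j * eta), axis=0)
    etap = eta - np.sum(b * np.cos(2 * j * xi) * np.sinh(2 * j * eta), axis=0)

    taup = np.sin(xip) / np.hypot(np.sinh(etap), np.cos(xip))
    lam = np.arctan2(np.sinh(etap), np.cos(xip))

    # invert tau' -> tau by Newton iteration (converges in ~3 steps)
    tau = taup.copy() if taup.ndim else np.array(taup, dtype=float)
    for _ in range(6):
        sigma = np.sinh(_E * np.arctanh(_E * tau / np.sqrt(1.0 + tau**2)))
        f = tau * np.sqrt(1.0 + sigma**2) - sigma * np.sqrt(1.0 + tau**2) - taup
        df = (np.sqrt((1.0 + sigma**2) * (1.0 + tau**2)) - sigma * tau) \
            * (1.0 - _E**2) * np.sqrt(1.0 + tau**2) / (1.0 + (1.0 - _E**2) * tau**2)
        tau = tau - f / df

    lon = np.degrees(lam) + utm_zone_central_meridian(zone)
    lat = np.degrees(np.arctan(tau))
    if lon.ndim == 0:
        return float(lon), float(lat)
    return lon, lat


def wrap_angle_deg(angle):
    """Wrap an angle (or array) in degrees to the interval (-180, 180]."""
    a = np.asarray(angle, dtype=float)
    wrapped = -np.mod(-a + 180.0, 360.0) + 180.0
    if wrapped.ndim == 0:
        return float(wrapped)
    return wrapped


def heading_deg(d_east, d_north):
    """Heading in degrees clockwise from grid north, in [0, 360)."""
    h = np.degrees(np.arctan2(np.asarray(d_east, float), np.asarray(d_north, float)))
    h = np.mod(h, 360.0)
    if h.ndim == 0:
        return float(h)
    return h
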