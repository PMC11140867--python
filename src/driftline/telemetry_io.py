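"""I/O and spatial primitives for GPS fix tables, bathymetry and tide data.

Fix tables live in memory as pandas DataFrames with the canonical columns
``fix_id, turtle_id, timestamp (UTC), lon, lat, hdop, water_temp_C`` and,
after projection, ``easting, northing`` in UTM meters.  Bathymetry is a
single-band grid of elevations in meters relative to Mean Sea Level
(negative below water), serialized as Arc/Info ASCII grid text.  Tide and
temperature series are two-column CSV (ISO-8601 UTC timestamp, value).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geodesy import geographic_to_utm, utm_to_geographic

FIX_COLUMNS = ["fix_id", "turtle_id", "timestamp", "lon", "lat", "hdop", "water_temp_C"]

DEFAULT_SCHEMA_MAP = {
    "turtle_id": "turtle_id",
    "timestamp": "timestamp",
    "lon": "lon",
    "lat": "lat",
    "hdop": "hdop",
    "water_temp_C": "water_temp_C",
}

#: sampling status codes returned by :func:`sample_raster`
SAMPLE_OK = "ok"
SAMPLE_NEAREST = "nearest"       # a nodata neighbor; nearest valid cell used
SAMPLE_OUT_OF_BOUNDS = "oob"


class SchemaError(ValueError):
    """A mandatory column is missing from an input fix table."""


@dataclass
class BathymetryGrid:
    """Regular grid of MSL elevations (m, negative below sea level).

    ``elevation[0, 0]`` is the south-west cell; rows increase northward.
    ``origin`` is the south-west *corner* of the grid; cell centers sit at
    ``origin + (i + 0.5) * cell_size``.
    """

    origin_easting: float
    origin_northing: float
    cell_size: float
    elevation: np.ndarray  # (n_rows, n_cols)
    crs_id: str = "EPSG:26916"
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        self.elevation = np.asarray(self.elevation, dtype=float)

    @property
    def n_rows(self) -> int:
        return self.elevation.shape[0]

    @property
    def n_cols(self) -> int:
        return self.elevation.shape[1]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(min_easting, min_northing, max_easting, max_northing)."""
        return (self.origin_easting, self.origin_northing,
                self.origin_easting + self.n_cols * self.cell_size,
                self.origin_northing + self.n_rows * self.cell_size)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        cs = self.cell_size
        x = self.origin_easting + (np.arange(self.n_cols) + 0.5) * cs
        y = self.origin_northing + (np.arange(self.n_rows) + 0.5) * cs
        return x, y


@dataclass
class TideSeries:
    """Hourly water levels in meters relative to MSL."""

    timestamps: pd.DatetimeIndex
    water_level_m: np.ndarray
    gaps: pd.DatetimeIndex = field(default_factory=lambda: pd.DatetimeIndex([], tz="UTC"))

    def __post_init__(self) -> None:
        ts = pd.DatetimeIndex(self.timestamps)
        if ts.tz is None:
            ts = ts.tz_localize("UTC")
        self.timestamps = ts
        self.water_level_m = np.asarray(self.water_level_m, dtype=float)
        if len(ts) > 1:
            steps = np.diff(ts.asi8) / 1e9
            if not np.allclose(steps, 3600.0):
                self.gaps = ts[1:][steps != 3600.0]

    def level_at(self, times, max_gap_min: float = 30.0) -> np.ndarray:
        """Water level at arbitrary times via nearest-hour lookup.

        Times farther than ``max_gap_min`` from any gauge record get NaN
        rather than an extrapolated level.
        """
        t = pd.DatetimeIndex(pd.to_datetime(times, utc=True))
        idx = np.searchsorted(self.timestamps.asi8, t.asi8)
        idx = np.clip(idx, 1, len(self.timestamps) - 1)
        left = np.abs(t.asi8 - self.timestamps.asi8[idx - 1])
        right = np.abs(self.timestamps.asi8[idx] - t.asi8)
        nearest = np.where(left <= right, idx - 1, idx)
        dist_s = np.minimum(left, right) / 1e9
        out = self.water_level_m[nearest].astype(float)
        out[dist_s > max_gap_min * 60.0] = np.nan
        return out


@dataclass
class FixReadResult:
    fixes: pd.DataFrame
    rejected: pd.DataFrame  # columns: line, reason

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)


def read_fixes(path, schema_map: dict[str, str] | None = None) -> FixReadResult:
    """Read a delimited fix table, reporting (not dropping) malformed rows.

    ``schema_map`` maps canonical field names to the file's column names for
    foreign exports; timestamp, lon, lat and turtle_id are mandatory.
    """
    smap = dict(DEFAULT_SCHEMA_MAP, **(schema_map or {}))
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    for canon in ("turtle_id", "timestamp", "lon", "lat"):
        if smap[canon] not in raw.columns:
            raise SchemaError(
                f"mandatory column '{smap[canon]}' (for field '{canon}') "
                f"not found; file has {list(raw.columns)}"
            )

    ts = pd.to_datetime(raw[smap["timestamp"]], utc=True, errors="coerce",
                        format="ISO8601")
    lon = pd.to_numeric(raw[smap["lon"]], errors="coerce")
    lat = pd.to_numeric(raw[smap["lat"]], errors="coerce")

    reasons = pd.Series("", index=raw.index, dtype=object)
    reasons[ts.isna()] = "unparseable timestamp"
    reasons[lon.isna() | lat.isna()] = "unparseable coordinate"
    reasons[(lat < -90) | (lat > 90) | (lon < -180) | (lon > 180)] = "coordinate out of range"
    bad = reasons != ""

    rejected = pd.DataFrame({
        "line": raw.index[bad] + 2,  # 1-based, after the header line
        "reason": reasons[bad].values,
    })

    fixes = pd.DataFrame({
        "turtle_id": raw.loc[~bad, smap["turtle_id"]].values,
        "timestamp": ts[~bad].values,
        "lon": lon[~bad].values,
        "lat": lat[~bad].values,
    })
    if smap["hdop"] in raw.columns:
        fixes["hdop"] = pd.to_numeric(raw.loc[~bad, smap["hdop"]], errors="coerce").values
    else:
        fixes["hdop"] = np.nan
    if smap["water_temp_C"] in raw.columns:
        fixes["water_temp_C"] = pd.to_numeric(
            raw.loc[~bad, smap["water_temp_C"]], errors="coerce").values
    else:
        fixes["water_temp_C"] = np.nan

    fixes = fixes.sort_values(["turtle_id", "timestamp"], kind="stable").reset_index(drop=True)
    fixes.insert(0, "fix_id", np.arange(len(fixes)))
    return FixReadResult(fixes=fixes, rejected=rejected.reset_index(drop=True))


def write_fixes(fixes: pd.DataFrame, path) -> None:
    out = fixes.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"], utc=True).dt.strftime(
        "%Y-%m-%dT%H:%M:%S%z")
    out.to_csv(path, index=False)


def project_fixes(fixes: pd.DataFrame, zone: int = 16) -> pd.DataFrame:
    """Add UTM ``easting``/``northing`` columns (meters) to a fix table."""
    out = fixes.copy()
    e, n = geographic_to_utm(out["lon"].to_numpy(), out["lat"].to_numpy(), zone=zone)
    out["easting"] = e
    out["northing"] = n
    return out


def unproject(easting, northing, zone: int = 16):
    """Inverse of :func:`project_fixes` for raw coordinate arrays."""
    return utm_to_geographic(easting, northing, zone=zone)


def sample_raster(grid: BathymetryGrid, easting, northing
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Bilinearly sample grid elevations at projected points.

    Returns ``(values, status)``; status is ``"ok"`` for a clean bilinear
    value, ``"nearest"`` when a nodata neighbor forced a nearest-valid-cell
    fallback, and ``"oob"`` (value NaN) outside the raster bounds.
    """
    e = np.atleast_1d(np.asarray(easting, dtype=float))
    n = np.atleast_1d(np.asarray(northing, dtype=float))
    cs = grid.cell_size
    # fractional cell-center coordinates
    fx = (e - grid.origin_easting) / cs - 0.5
    fy = (n - grid.origin_northing) / cs - 0.5

    values = np.full(e.shape, np.nan)
    status = np.full(e.shape, SAMPLE_OUT_OF_BOUNDS, dtype=object)
    xmin, ymin, xmax, ymax = grid.extent
    inb = (e >= xmin) & (e <= xmax) & (n >= ymin) & (n <= ymax)
    if not inb.any():
        return values, status

    x0 = np.clip(np.floor(fx[inb]).astype(int), 0, grid.n_cols - 2)
    y0 = np.clip(np.floor(fy[inb]).astype(int), 0, grid.n_rows - 2)
    tx = np.clip(fx[inb] - x0, 0.0, 1.0)
    ty = np.clip(fy[inb] - y0, 0.0, 1.0)

    z = grid.elevation
    q = np.stack([z[y0, x0], z[y0, x0 + 1], z[y0 + 1, x0], z[y0 + 1, x0 + 1]])
    valid = q != grid.nodata
    bilin = (q[0] * (1 - tx) * (1 - ty) + q[1] * tx * (1 - ty)
             + q[2] * (1 - tx) * ty + q[3] * tx * ty)

    all_valid = valid.all(axis=0)
    res = np.where(all_valid, bilin, np.nan)
    st = np.where(all_valid, SAMPLE_OK, SAMPLE_NEAREST).astype(object)

    # nodata fallback: nearest valid cell over the whole grid
    if (~all_valid).any():
        vy, vx = np.nonzero(z != grid.nodata)
        if len(vx) == 0:
            raise ValueError("raster contains only nodata cells")
        xs, ys = grid.cell_centers()
        for k in np.nonzero(~all_valid)[0]:
            pe = e[inb][k]
            pn = n[inb][k]
            d2 = (xs[vx] - pe) ** 2 + (ys[vy] - pn) ** 2
            j = int(np.argmin(d2))
            res[k] = z[vy[j], vx[j]]
    values[inb] = res
    status[inb] = st
    return values, status


def write_ascii_grid(grid: BathymetryGrid, path) -> None:
    """Serialize a grid to Arc/Info ASCII format (rows north to south)."""
    header = (f"ncols {grid.n_cols}\nnrows {grid.n_rows}\n"
              f"xllcorner {grid.origin_easting!r}\nyllcorner {grid.origin_northing!r}\n"
              f"cellsize {grid.cell_size!r}\nNODATA_value {grid.nodata!r}\n")
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, grid.elevation[::-1], fmt="%.6g")


def read_ascii_grid(path, crs_id: str = "EPSG:26916") -> BathymetryGrid:
    with open(path) as fh:
        hdr = {}
        for _ in range(6):
            key, val = fh.readline().split()
            hdr[key.lower()] = float(val)
        data = np.loadtxt(fh)
    data = np.atleast_2d(data)[::-1]
    return BathymetryGrid(
        origin_easting=hdr["xllcorner"], origin_northing=hdr["yllcorner"],
        cell_size=hdr["cellsize"], elevation=data, crs_id=crs_id,
        nodata=hdr.get("nodata_value", -9999.0),
    )


def read_series_csv(path, value_col: str | None = None) -> pd.DataFrame:
    """Read a 2-column (timestamp, value) CSV; returns a UTC-indexed frame."""
    df = pd.read_csv(path)
    tcol = df.columns[0]
    vcol = value_col or df.columns[1]
    df[tcol] = pd.to_datetime(df[tcol], utc=True)
    return df.rename(columns={tcol: "timestamp", vcol: "value"})[["timestamp", "value"]]


def read_tide(path) -> TideSeries:
    df = read_series_csv(path)
    return TideSeries(timestamps=pd.DatetimeIndex(df["timestamp"]),
                      water_level_m=df["value"].to_numpy())


def write_series_csv(timestamps, values, path, value_name: str = "value") -> None:
    pd.DataFrame({
        "timestamp": pd.DatetimeIndex(pd.to_datetime(timestamps, utc=True)).strftime(
            "%Y-%m-%dT%H:%M:%S%z"),
        value_name: values,
    }).to_csv(path, index=False)
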