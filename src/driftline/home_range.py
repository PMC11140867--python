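"""Line-based kernel home ranges: density surfaces, isopleths, overlap.

The utilization surface is a Gaussian kernel density (σ = 150 m by
default) applied to *travel lines* rather than points: each retained
segment is discretized into points spaced at most half a grid cell apart,
each carrying its share of the segment's length, and the resulting
length-weighted point mass is smoothed with an isotropic Gaussian.  Cell
values are track-length density in meters of path per square meter, so the
surface integrates to the total selected track length (mass conservation
is a tested invariant, within 0.5% on a grid padded 4σ beyond the data;
no edge correction is applied).

Segments entering the density are restricted to slow, short, well-sampled
movements — speed ≤ 0.08 km/h, length ≤ 320 m, duration ≤ 4 h — so the
surface reflects occupancy rather than transit.

A p% home range is the smallest-area set of grid cells containing p% of
the surface mass: cells are ranked by density and accumulated until the
target mass is reached; ties at the resulting level are included.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from shapely.geometry import Point
from shapely.prepared import prep

logger = logging.getLogger(__name__)

SIGMA_M_DEFAULT = 150.0
CELL_SIZE_M_DEFAULT = 25.0
HR_SPEED_MAX_KMH = 0.08
HR_LENGTH_MAX_M = 320.0
HR_DURATION_MAX_H = 4.0
PAD_SIGMAS = 4.0


@dataclass
class DensitySurface:
    """Gridded track-length density (m of path per m²)."""

    origin_easting: float
    origin_northing: float
    cell_size: float
    values: np.ndarray  # (n_rows, n_cols), row 0 = south
    total_mass: float   # total selected track length, m

    @property
    def cell_area(self) -> float:
        return self.cell_size ** 2

    @property
    def grid_mass(self) -> float:
        return float(self.values.sum() * self.cell_area)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        cs = self.cell_size
        x = self.origin_easting + (np.arange(self.values.shape[1]) + 0.5) * cs
        y = self.origin_northing + (np.arange(self.values.shape[0]) + 0.5) * cs
        return x, y

    def same_grid(self, other: "DensitySurface") -> bool:
        return (self.values.shape == other.values.shape
                and np.isclose(self.cell_size, other.cell_size)
                and np.isclose(self.origin_easting, other.origin_easting)
                and np.isclose(self.origin_northing, other.origin_northing))


@dataclass
class HomeRange:
    """A percentile isopleth of a density surface."""

    turtle_id: str
    percentile: float
    level: float          # density threshold λ_p
    mask: np.ndarray      # boolean, same grid as the source surface
    origin_easting: float
    origin_northing: float
    cell_size: float

    @property
    def area_km2(self) -> float:
        return float(self.mask.sum()) * self.cell_size ** 2 / 1e6

    def clipped(self, polygon) -> "HomeRange":
        """Intersect the mask with a (projected) water/bay polygon."""
        prepared = prep(polygon)
        cs = self.cell_size
        ys, xs = np.nonzero(self.mask)
        keep = np.array([
            prepared.intersects(Point(self.origin_easting + (x + 0.5) * cs,
                                      self.origin_northing + (y + 0.5) * cs))
            for y, x in zip(ys, xs)
        ], dtype=bool) if len(ys) else np.array([], dtype=bool)
        mask = np.zeros_like(self.mask)
        mask[ys[keep], xs[keep]] = True
        return HomeRange(self.turtle_id, self.percentile, self.level, mask,
                         self.origin_easting, self.origin_northing, cs)


def select_hr_segments(segments: pd.DataFrame,
                       vmax_kmh: float = HR_SPEED_MAX_KMH,
                       length_max_m: float = HR_LENGTH_MAX_M,
                       duration_max_h: float = HR_DURATION_MAX_H) -> pd.DataFrame:
    """Keep segments with speed ≤ 0.08 km/h, length ≤ 320 m and Δt ≤ 4 h."""
    keep = ((segments["speed_kmh"] <= vmax_kmh)
            & (segments["length_m"] <= length_max_m)
            & (segments["duration_h"] <= duration_max_h))
    return segments.loc[keep].reset_index(drop=True)


def _snap_bounds(xmin, ymin, xmax, ymax, cell_size):
    xmin = np.floor(xmin / cell_size) * cell_size
    ymin = np.floor(ymin / cell_size) * cell_size
    xmax = np.ceil(xmax / cell_size) * cell_size
    ymax = np.ceil(ymax / cell_size) * cell_size
    return xmin, ymin, xmax, ymax


def line_kde(segments: pd.DataFrame, sigma_m: float = SIGMA_M_DEFAULT,
             cell_size_m: float = CELL_SIZE_M_DEFAULT,
             bounds: tuple[float, float, float, float] | None = None
             ) -> DensitySurface | None:
    """Gaussian line-kernel density of segments on a padded metric grid.

    ``bounds`` (xmin, ymin, xmax, ymax) fixes the grid explicitly — use one
    common bounds for all turtles when surfaces must be compared or
    overlaid; padding of 4σ is added in either case.  Returns None (with a
    log entry) when no segment carries positive length.
    """
    if len(segments) == 0 or segments["length_m"].sum() <= 0:
        logger.info("line_kde: empty segment selection, no surface produced")
        return None
    x0 = segments["start_easting"].to_numpy(float)
    y0 = segments["start_northing"].to_numpy(float)
    x1 = segments["end_easting"].to_numpy(float)
    y1 = segments["end_northing"].to_numpy(float)
    lengths = segments["length_m"].to_numpy(float)

    if bounds is None:
        bounds = (min(x0.min(), x1.min()), min(y0.min(), y1.min()),
                  max(x0.max(), x1.max()), max(y0.max(), y1.max()))
    pad = PAD_SIGMAS * sigma_m
    xmin, ymin, xmax, ymax = _snap_bounds(
        bounds[0] - pad, bounds[1] - pad, bounds[2] + pad, bounds[3] + pad,
        cell_size_m)
    n_cols = int(round((xmax - xmin) / cell_size_m))
    n_rows = int(round((ymax - ymin) / cell_size_m))

    # discretize each segment into points ≤ cell/2 apart, weights = length share
    max_spacing = cell_size_m / 2.0
    pts_x, pts_y, pts_w = [], [], []
    for xa, ya, xb, yb, L in zip(x0, y0, x1, y1, lengths):
        k = max(int(np.ceil(L / max_spacing)), 1)
        f = (np.arange(k) + 0.5) / k
        pts_x.append(xa + f * (xb - xa))
        pts_y.append(ya + f * (yb - ya))
        pts_w.append(np.full(k, L / k))
    px = np.concatenate(pts_x)
    py = np.concatenate(pts_y)
    pw = np.concatenate(pts_w)

    ix = np.clip(((px - xmin) / cell_size_m).astype(int), 0, n_cols - 1)
    iy = np.clip(((py - ymin) / cell_size_m).astype(int), 0, n_rows - 1)
    mass = np.zeros((n_rows, n_cols))
    np.add.at(mass, (iy, ix), pw)

    smoothed = gaussian_filter(mass, sigma=sigma_m / cell_size_m,
                               mode="constant", cval=0.0)
    return DensitySurface(origin_easting=xmin, origin_northing=ymin,
                          cell_size=cell_size_m,
                          values=smoothed / cell_size_m ** 2,
                          total_mass=float(lengths.sum()))


def isopleth(surface: DensitySurface, p: float,
             turtle_id: str = "") -> HomeRange:
    """p% home range: highest-density cells holding ≥ p% of surface mass."""
    if not 0.0 < p <= 100.0:
        raise ValueError(f"percentile must be in (0, 100], got {p}")
    if surface.grid_mass <= 0:
        raise ValueError("cannot take an isopleth of a massless surface")
    flat = np.sort(surface.values.ravel())[::-1]
    cum = np.cumsum(flat) * surface.cell_area
    target = p / 100.0 * surface.grid_mass
    k = int(np.searchsorted(cum, target * (1 - 1e-12)))
    k = min(k, len(flat) - 1)
    level = flat[k]
    if p >= 100.0:
        mask = surface.values > 0
        level = 0.0
    else:
        mask = surface.values >= level
    return HomeRange(turtle_id=turtle_id, percentile=p, level=float(level),
                     mask=mask, origin_easting=surface.origin_easting,
                     origin_northing=surface.origin_northing,
                     cell_size=surface.cell_size)


def overlap_table(homeranges: list[HomeRange]) -> pd.DataFrame:
    """Shared-space accounting across turtles on one common grid.

    Returns one row per occupancy count k = 1..n with the area (km²) of
    cells inside exactly k turtles' isopleths and its share of the union
    area; the k = 1 share is the percent of non-overlapping range.
    """
    if not homeranges:
        raise ValueError("no home ranges supplied")
    shapes = {hr.mask.shape for hr in homeranges}
    origins = {(round(hr.origin_easting, 6), round(hr.origin_northing, 6),
                round(hr.cell_size, 6)) for hr in homeranges}
    if len(shapes) > 1 or len(origins) > 1:
        raise ValueError("home ranges are not on a common grid; "
                         "rebuild surfaces with shared bounds")
    counts = np.sum([hr.mask.astype(int) for hr in homeranges], axis=0)
    cell_km2 = homeranges[0].cell_size ** 2 / 1e6
    union_area = float((counts > 0).sum()) * cell_km2
    rows = []
    for k in range(1, len(homeranges) + 1):
        area = float((counts == k).sum()) * cell_km2
        rows.append({"n_turtles": k, "area_km2": area,
                     "percent_of_union": 100.0 * area / union_area if union_area else 0.0})
    return pd.DataFrame(rows)


def diel_homerange(segments: pd.DataFrame, diel_base: str, p: float,
                   turtle_id: str = "", sigma_m: float = SIGMA_M_DEFAULT,
                   cell_size_m: float = CELL_SIZE_M_DEFAULT,
                   bounds=None) -> HomeRange | None:
    """Home range restricted to segments of one diel class (day or night)."""
    sub = segments.loc[segments["diel_base"] == diel_base]
    if len(sub) < 2:
        logger.info("diel_homerange: class %r has %d segments, excluded",
                    diel_base, len(sub))
        return None
    selected = select_hr_segments(sub)
    surface = line_kde(selected, sigma_m=sigma_m, cell_size_m=cell_size_m,
                       bounds=bounds)
    if surface is None:
        return None
    return isopleth(surface, p, turtle_id=turtle_id)
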