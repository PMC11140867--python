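"""Synthetic coastal bay, tides, temperature, turtle movement and GPS tags.

This module builds a miniature world with the statistical structure the
analysis pipeline assumes, so every downstream stage can be validated
against known ground truth:

* a bathymetry of a shallow shoal band cut by deeper channels next to a
  deep basin, with a gulf strip outside the bay mouth;
* a semidiurnal tide and a seasonal water-temperature cycle;
* turtles following one of two archetypes — deep-basin residents, or diel
  movers that cross onto the shoal at night (preferentially at high tide)
  — with occasional multi-day "drifting" bouts whose probability rises in
  cold water, and optional winter excursions into the gulf;
* an hourly GPS observation process with day/night-dependent fix success,
  Gaussian position error, and the three corruption types the QC filters
  target (high-HDOP fixes, near-duplicate fixes, gross position outliers).

Drifting bouts are bracketed by short directed transits: the turtle swims
out to the drift line before going passive and swims back afterwards.
Besides being the natural reading of drift as current-riding, this gives
ground-truth bout boundaries an observable movement signature.

Ground truth (true positions, behavior states, drift bout intervals) is
returned in sidecar tables keyed by fix id; analysis modules never read
it — only tests do.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import box

from .geodesy import utm_to_geographic
from .solar_diel import sun_times
from .telemetry_io import BathymetryGrid, TideSeries

DEEP_RESIDENT = "DEEP_RESIDENT"
SHOAL_FORAGE = "SHOAL_FORAGE"
TRANSIT = "TRANSIT"
DRIFT = "DRIFT"
GULF = "GULF"

# internal movement modes (recorded behavior is the coarser enum above)
_M_RESIDENT, _M_TO_SHOAL, _M_SHOAL, _M_FROM_SHOAL = 0, 1, 2, 3
_M_DRIFT_ENTRY, _M_DRIFT, _M_DRIFT_EXIT = 4, 5, 6
_M_TO_GULF, _M_GULF, _M_FROM_GULF = 7, 8, 9

_MODE_BEHAVIOR = {
    _M_RESIDENT: DEEP_RESIDENT, _M_TO_SHOAL: TRANSIT, _M_SHOAL: SHOAL_FORAGE,
    _M_FROM_SHOAL: TRANSIT, _M_DRIFT_ENTRY: TRANSIT, _M_DRIFT: DRIFT,
    _M_DRIFT_EXIT: TRANSIT, _M_TO_GULF: GULF, _M_GULF: GULF, _M_FROM_GULF: GULF,
}


@dataclass
class SimConfig:
    """Study conditions for the synthetic world.

    Geometry is in UTM zone 16N meters, sized like a small Gulf-coast bay:
    a shoal band (~1 m deep) along the eastern shore cut by ~6 m channels,
    a ~6 m basin, and a deeper gulf strip west of the bay.  Tag behavior
    follows an hourly fix schedule with markedly lower daytime success.
    """

    seed: int = 0
    n_turtles: int = 10
    start_time: str = "2019-01-01"
    end_time: str = "2019-04-01"

    # world geometry (m)
    bay_origin_easting: float = 654_000.0
    bay_origin_northing: float = 3_284_000.0
    bay_width_m: float = 10_000.0
    bay_height_m: float = 12_000.0
    gulf_margin_m: float = 4_000.0
    bathy_cell_m: float = 50.0
    shoal_depth_m: float = 1.0
    channel_depth_m: float = 6.0
    gulf_depth_m: float = 10.0
    shoal_band_fraction: float = 0.25
    n_channels: int = 3
    channel_width_m: float = 400.0

    # tide (semidiurnal) and seasonal temperature
    tide_amplitude_m: float = 0.3
    tide_period_h: float = 12.42
    tide_phase_rad: float = 0.0
    temp_winter_C: float = 14.0
    temp_summer_C: float = 30.0
    temp_peak_doy: float = 200.0

    # GPS observation process
    day_detection_prob: float = 0.45
    night_detection_prob: float = 0.9
    gps_cep50_m: float = 6.0
    p_hdop_fail: float = 0.02
    p_duplicate: float = 0.05
    p_outlier: float = 0.01
    hdop_fail_error_m: float = 300.0
    outlier_offset_m: float = 6_000.0

    # movement (internal step; speeds km/h as lognormal(median, sigma_log);
    # turning-angle std in degrees per step)
    step_min: float = 6.0
    state_speed_params: dict = field(default_factory=lambda: {
        DEEP_RESIDENT: (0.08, 0.7),
        SHOAL_FORAGE: (0.105, 0.6),
        TRANSIT: (0.45, 0.2),
        DRIFT: (0.045, 0.08),
        GULF: (0.24, 0.6),
    })
    state_turn_sd_deg: dict = field(default_factory=lambda: {
        DEEP_RESIDENT: 60.0, SHOAL_FORAGE: 45.0, TRANSIT: 5.0,
        DRIFT: 0.6, GULF: 20.0,
    })

    # ectotherm physiology: active swimming speed scales by this fraction
    # per °C around the seasonal mean (passive drift is unaffected)
    temp_speed_coef_per_C: float = 0.02

    # drifting: stationary time-fraction anchors by temperature, bout shape
    drift_prob_cold: float = 0.362
    drift_prob_warm: float = 0.047
    drift_cold_C: float = 16.0
    drift_warm_C: float = 28.0
    drift_bout_min_h: float = 12.0
    drift_bout_max_h: float = 120.0
    drift_bout_mean_h: float = 30.0
    drift_entry_transit_h: float = 4.0
    drift_exit_transit_h: float = 3.0

    # diel shoal use
    tide_gate_level_m: float = 0.0
    behavior_switch_jitter_min: float = 30.0

    # gulf excursions
    gulf_trigger_C: float = 16.0
    gulf_trigger_h: float = 72.0
    gulf_stay_days: float = 40.0

    archetypes: list | None = None  # "deep_resident"/"diel_mover" (+"+gulf")

    def __post_init__(self) -> None:
        for name in ("day_detection_prob", "night_detection_prob",
                     "p_hdop_fail", "p_duplicate", "p_outlier",
                     "drift_prob_cold", "drift_prob_warm"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.night_detection_prob < self.day_detection_prob:
            raise ValueError("night detection probability must be >= day "
                             "(tags fix far less often in daytime)")
        if self.drift_prob_cold <= self.drift_prob_warm:
            raise ValueError("drifting must be more frequent in cold water "
                             "(drift_prob_cold > drift_prob_warm)")
        if self.bay_width_m <= 0 or self.bay_height_m <= 0:
            raise ValueError(
                f"degenerate bay extent {self.bay_width_m} x {self.bay_height_m} m; "
                "both dimensions must be positive")
        for dim in ("bay_width_m", "bay_height_m", "gulf_margin_m"):
            if getattr(self, dim) % self.bathy_cell_m != 0:
                raise ValueError(
                    f"{dim}={getattr(self, dim)} is not a multiple of "
                    f"bathy_cell_m={self.bathy_cell_m}")
        if self.tide_amplitude_m < 0:
            raise ValueError("tide_amplitude_m must be >= 0")

    @property
    def start(self) -> pd.Timestamp:
        return pd.Timestamp(self.start_time, tz="UTC")

    @property
    def end(self) -> pd.Timestamp:
        return pd.Timestamp(self.end_time, tz="UTC")

    @property
    def world_origin_easting(self) -> float:
        return self.bay_origin_easting - self.gulf_margin_m

    def default_archetypes(self) -> list[str]:
        """Roughly 30% basin residents, the rest diel movers; about a third
        of turtles (cycling) may leave for the gulf in cold snaps."""
        out = []
        for i in range(self.n_turtles):
            base = "deep_resident" if i % 10 in (0, 4, 8) else "diel_mover"
            if i % 10 in (1, 5, 9):
                base += "+gulf"
            out.append(base)
        return out


def make_bathymetry(config: SimConfig) -> BathymetryGrid:
    """Shoal band along the bay's eastern edge, channels through it, deep
    basin elsewhere, and a deeper gulf strip west of the bay."""
    cs = config.bathy_cell_m
    n_cols = int(round((config.gulf_margin_m + config.bay_width_m) / cs))
    n_rows = int(round(config.bay_height_m / cs))
    if n_cols < 2 or n_rows < 2:
        raise ValueError(
            f"bathymetry grid would be {n_rows} x {n_cols} cells; extent too "
            f"small for cell size {cs} m")
    elev = np.full((n_rows, n_cols), -config.channel_depth_m)

    gulf_cols = int(round(config.gulf_margin_m / cs))
    elev[:, :gulf_cols] = -config.gulf_depth_m

    shoal_cols = int(round(config.shoal_band_fraction * config.bay_width_m / cs))
    elev[:, n_cols - shoal_cols:] = -config.shoal_depth_m

    # channels: east-west cuts through the shoal band at even spacing
    ch_rows = max(int(round(config.channel_width_m / cs)), 1)
    for k in range(config.n_channels):
        center = int(round((k + 1) * n_rows / (config.n_channels + 1)))
        lo = max(center - ch_rows // 2, 0)
        elev[lo:lo + ch_rows, n_cols - shoal_cols:] = -config.channel_depth_m

    return BathymetryGrid(
        origin_easting=config.world_origin_easting,
        origin_northing=config.bay_origin_northing,
        cell_size=cs, elevation=elev)


def bay_polygon(config: SimConfig):
    """The bay proper (excludes the gulf strip), as a projected rectangle."""
    return box(config.bay_origin_easting, config.bay_origin_northing,
               config.bay_origin_easting + config.bay_width_m,
               config.bay_origin_northing + config.bay_height_m)


def make_tide(config: SimConfig, pad_h: float = 2.0) -> TideSeries:
    """Hourly semidiurnal water level, MSL-referenced (zero mean)."""
    t = pd.date_range(config.start - pd.Timedelta(hours=pad_h),
                      config.end + pd.Timedelta(hours=pad_h), freq="h")
    hours = (t - config.start) / pd.Timedelta(hours=1)
    level = config.tide_amplitude_m * np.sin(
        2 * np.pi * hours.to_numpy() / config.tide_period_h + config.tide_phase_rad)
    return TideSeries(timestamps=t, water_level_m=level)


def tide_level(config: SimConfig, times) -> np.ndarray:
    """Exact (continuous) tide level at arbitrary UTC times."""
    t = pd.DatetimeIndex(pd.to_datetime(times, utc=True))
    hours = (t - config.start) / pd.Timedelta(hours=1)
    return config.tide_amplitude_m * np.sin(
        2 * np.pi * np.asarray(hours, float) / config.tide_period_h
        + config.tide_phase_rad)


def water_temperature(config: SimConfig, times) -> np.ndarray:
    """Seasonal sinusoid between the winter and summer anchors (°C)."""
    t = pd.DatetimeIndex(pd.to_datetime(times, utc=True))
    doy = t.dayofyear.to_numpy() + (t.hour.to_numpy() / 24.0)
    mean = 0.5 * (config.temp_winter_C + config.temp_summer_C)
    amp = 0.5 * (config.temp_summer_C - config.temp_winter_C)
    return mean + amp * np.cos(2 * np.pi * (doy - config.temp_peak_doy) / 365.25)


def _drift_fraction(config: SimConfig, temp_C: float) -> float:
    """Target stationary drift time-fraction, linear in temperature."""
    t0, t1 = config.drift_cold_C, config.drift_warm_C
    f0, f1 = config.drift_prob_cold, config.drift_prob_warm
    w = np.clip((temp_C - t0) / (t1 - t0), 0.0, 1.0)
    return float(f0 + (f1 - f0) * w)


def _night_table(config: SimConfig) -> list[tuple[pd.Timestamp, pd.Timestamp]]:
    """(sunrise, sunset) per date at the bay center."""
    cx = config.bay_origin_easting + config.bay_width_m / 2.0
    cy = config.bay_origin_northing + config.bay_height_m / 2.0
    lon, lat = utm_to_geographic(cx, cy)
    out = []
    for day in pd.date_range(config.start.normalize() - pd.Timedelta(days=1),
                             config.end.normalize() + pd.Timedelta(days=1)):
        out.append(sun_times(day.date(), lat, lon))
    return out


def _is_night_array(config: SimConfig, times: pd.DatetimeIndex) -> np.ndarray:
    events = _night_table(config)
    sunrises = pd.DatetimeIndex([e[0] for e in events])
    sunsets = pd.DatetimeIndex([e[1] for e in events])
    is_day = np.zeros(len(times), dtype=bool)
    for sr, ss in zip(sunrises, sunsets):
        is_day |= np.asarray(times >= sr) & np.asarray(times < ss)
    return ~is_day


def simulate_tracks(config: SimConfig, bathy: BathymetryGrid,
                    tide: TideSeries | None = None
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate true turtle states at the internal (6 min) step.

    Returns ``(states, drift_bouts)``: per-step true positions with behavior
    labels, speeds and tide-corrected depths; and the ground-truth drift
    bout intervals (the passive phase only, excluding the entry/exit
    transits).  Deterministic for a fixed config seed.
    """
    shoal_mask = bathy.elevation >= -(config.shoal_depth_m + 0.01)
    if not shoal_mask.any():
        raise ValueError("bathymetry has no shoal band; diel movers would "
                         "have no reachable foraging habitat")
    sy, sx = np.nonzero(shoal_mask)
    xs_c, ys_c = bathy.cell_centers()
    shoal_x, shoal_y = xs_c[sx], ys_c[sy]

    dt_h = config.step_min / 60.0
    times = pd.date_range(config.start, config.end, freq=f"{config.step_min}min",
                          inclusive="left")
    n_steps = len(times)
    night = _is_night_array(config, times)
    tide_lv = tide_level(config, times)
    temp = water_temperature(config, times)
    jitter_h = config.behavior_switch_jitter_min / 60.0

    bay_x0 = config.bay_origin_easting
    bay_x1 = bay_x0 + config.bay_width_m
    bay_y0 = config.bay_origin_northing
    bay_y1 = bay_y0 + config.bay_height_m
    world_x0 = config.world_origin_easting
    shoal_edge_x = bay_x1 - config.shoal_band_fraction * config.bay_width_m

    archetypes = config.archetypes or config.default_archetypes()
    if len(archetypes) != config.n_turtles:
        raise ValueError("archetypes list length must equal n_turtles")

    speed_med = {b: p[0] for b, p in config.state_speed_params.items()}
    speed_sig = {b: p[1] for b, p in config.state_speed_params.items()}
    turn_sd = config.state_turn_sd_deg

    all_states = []
    bout_rows = []

    for ti in range(config.n_turtles):
        rng = np.random.default_rng([config.seed % (2**31), ti])
        arch = archetypes[ti]
        is_mover = arch.startswith("diel_mover")
        gulf_capable = arch.endswith("+gulf")

        # movers live near the shoal edge (a nightly round trip at transit
        # speed must fit inside a night); residents anywhere in the basin
        y = rng.uniform(bay_y0 + 0.15 * config.bay_height_m,
                        bay_y1 - 0.15 * config.bay_height_m)
        if is_mover:
            x = shoal_edge_x - rng.uniform(300.0, 800.0)
        else:
            x = rng.uniform(bay_x0 + 0.15 * config.bay_width_m,
                            shoal_edge_x - 1000.0)
        heading = rng.uniform(0, 2 * np.pi)
        mode = _M_RESIDENT
        mode_until = -1          # step index when a timed mode ends
        drift_seq = []           # pending (mode, n_steps) phases
        target = None            # (x, y) for directed modes
        home = (x, y)
        anchor = (x, y)          # long-term home-range center
        cold_h = 0.0
        bout_start_idx = None

        # a fixed nightly foraging patch a few hundred meters onto the shoal
        shoal_home = (shoal_edge_x + rng.uniform(200.0, 600.0),
                      min(max(y + rng.normal(0.0, 500.0), bay_y0 + 200.0),
                          bay_y1 - 200.0))

        # pre-drawn per-step noise (keeps the step loop cheap + deterministic)
        z_speed = rng.normal(0.0, 1.0, n_steps)
        z_turn = rng.normal(0.0, 1.0, n_steps)
        z_dir = rng.normal(0.0, 5.0, n_steps)
        u_hazard = rng.random(n_steps)

        xs = np.empty(n_steps)
        ys = np.empty(n_steps)
        beh = np.empty(n_steps, dtype=object)
        spd = np.empty(n_steps)

        for i in range(n_steps):
            T = temp[i]
            cold_h = cold_h + dt_h if T < config.gulf_trigger_C else 0.0

            # --- mode transitions -----------------------------------------
            if mode == _M_RESIDENT:
                f = _drift_fraction(config, T)
                hazard = f / ((1.0 - f) * config.drift_bout_mean_h)
                if u_hazard[i] < hazard * dt_h:
                    bout_h = min(config.drift_bout_min_h + rng.exponential(
                        config.drift_bout_mean_h - config.drift_bout_min_h),
                        config.drift_bout_max_h)
                    drift_seq = [
                        (_M_DRIFT, int(round(bout_h / dt_h))),
                        (_M_DRIFT_EXIT, int(round(config.drift_exit_transit_h / dt_h))),
                    ]
                    home = (x, y)
                    # swim out toward open water, then ride the along-bay
                    # current (drift continues on the entry heading)
                    to_center = np.arctan2(
                        0.5 * (bay_x0 + shoal_edge_x) - x,
                        0.5 * (bay_y0 + bay_y1) - y)
                    along_bay = 0.0 if rng.random() < 0.5 else np.pi
                    bias = (to_center - along_bay + np.pi) % (2 * np.pi) - np.pi
                    heading = (along_bay + 0.5 * np.clip(bias, -np.pi / 2, np.pi / 2)
                               + np.radians(rng.normal(0.0, 15.0)))
                    mode = _M_DRIFT_ENTRY
                    mode_until = i + int(round(config.drift_entry_transit_h / dt_h))
                elif (gulf_capable and cold_h > config.gulf_trigger_h):
                    mode = _M_TO_GULF
                    home = (x, y)
                    target = (world_x0 + config.gulf_margin_m / 2.0,
                              0.5 * (bay_y0 + bay_y1))
                    cold_h = 0.0
                elif (is_mover and night[i]
                      and tide_lv[i] > config.tide_gate_level_m):
                    mode = _M_TO_SHOAL
                    home = anchor
                    target = shoal_home
            elif mode == _M_SHOAL:
                if not night[i] or tide_lv[i] <= config.tide_gate_level_m:
                    mode = _M_FROM_SHOAL
                    target = home

            if mode in (_M_DRIFT_ENTRY, _M_DRIFT, _M_DRIFT_EXIT) and i >= mode_until:
                if mode == _M_DRIFT and bout_start_idx is not None:
                    bout_rows.append({
                        "turtle_id": f"T{ti:02d}",
                        "start_time": times[bout_start_idx],
                        "end_time": times[min(i, n_steps - 1)],
                    })
                    bout_start_idx = None
                if drift_seq:
                    mode, nst = drift_seq.pop(0)
                    mode_until = i + nst
                    if mode == _M_DRIFT:
                        bout_start_idx = i
                else:
                    mode = _M_RESIDENT

            if mode == _M_TO_SHOAL:
                if not night[i]:          # dawn before arrival: turn back
                    mode = _M_FROM_SHOAL
                    target = home
                elif np.hypot(x - target[0], y - target[1]) < 150.0:
                    mode = _M_SHOAL
            elif mode == _M_FROM_SHOAL and np.hypot(x - target[0], y - target[1]) < 150.0:
                mode = _M_RESIDENT
            elif mode == _M_TO_GULF and x < bay_x0 - 200.0:
                mode = _M_GULF
                mode_until = i + int(round(config.gulf_stay_days * 24 / dt_h))
            elif mode == _M_GULF and i >= mode_until:
                mode = _M_FROM_GULF
                target = home
            elif mode == _M_FROM_GULF and np.hypot(x - target[0], y - target[1]) < 300.0:
                mode = _M_RESIDENT

            # --- movement -------------------------------------------------
            behavior = _MODE_BEHAVIOR[mode]
            v = speed_med[behavior] * np.exp(speed_sig[behavior] * z_speed[i])
            if behavior != DRIFT:
                v *= max(1.0 + config.temp_speed_coef_per_C
                         * (T - 0.5 * (config.temp_winter_C + config.temp_summer_C)),
                         0.2)
            if mode in (_M_TO_SHOAL, _M_FROM_SHOAL, _M_TO_GULF, _M_FROM_GULF):
                bearing = np.arctan2(target[0] - x, target[1] - y)
                heading = bearing + np.radians(z_dir[i])
            else:
                heading = heading + np.radians(turn_sd[behavior] * z_turn[i])

            # drifting paths curve gently away from shores (along-bay
            # currents) instead of reflecting: an abrupt reversal mid-drift
            # would be unphysical for a passively transported animal
            if mode in (_M_DRIFT_ENTRY, _M_DRIFT):
                # drift curvature stays under ~4°/h so the coarse turning
                # angle of a drifting track never approaches the 20° scale;
                # the entry swim can steer harder (its speed is not drift-like
                # anyway), covering the rare start near a shore
                margin, max_rot_deg = ((1400.0, 0.4) if mode == _M_DRIFT
                                       else (700.0, 2.0))
                d_edge = min(x - bay_x0, shoal_edge_x - 150.0 - x,
                             y - bay_y0, bay_y1 - y)
                if d_edge < margin:
                    to_center = np.arctan2(
                        0.5 * (bay_x0 + shoal_edge_x) - x,
                        0.5 * (bay_y0 + bay_y1) - y)
                    diff = (to_center - heading + np.pi) % (2 * np.pi) - np.pi
                    max_rot = np.radians(max_rot_deg)
                    heading = heading + np.clip(diff, -max_rot, max_rot)

            step_m = v * 1000.0 * dt_h
            nx = x + step_m * np.sin(heading)
            ny = y + step_m * np.cos(heading)

            # containment: world edges; basin dwellers keep off the shoal,
            # only gulf modes may cross the bay mouth
            if mode == _M_GULF:
                x_lo, x_hi = world_x0, bay_x0
            elif mode in (_M_TO_GULF, _M_FROM_GULF):
                x_lo, x_hi = world_x0, bay_x1
            else:
                x_lo, x_hi = bay_x0, bay_x1
            if not (x_lo + 50 < nx < x_hi - 50) or not (bay_y0 + 50 < ny < bay_y1 - 50):
                heading = heading + np.pi + np.radians(4.0 * z_dir[i])
                nx, ny = x, y
            elif (mode in (_M_RESIDENT, _M_DRIFT_ENTRY, _M_DRIFT, _M_DRIFT_EXIT)
                  and nx > shoal_edge_x - 100.0):
                heading = heading + np.pi + np.radians(4.0 * z_dir[i])
                nx, ny = x, y
            elif mode == _M_SHOAL and nx < shoal_edge_x + 50.0:
                heading = heading + np.pi
                nx, ny = x, y
            x, y = nx, ny

            xs[i] = x
            ys[i] = y
            beh[i] = behavior
            spd[i] = v

        if mode == _M_DRIFT and bout_start_idx is not None:
            bout_rows.append({"turtle_id": f"T{ti:02d}",
                              "start_time": times[bout_start_idx],
                              "end_time": times[-1]})

        # true depth: cell elevation + tide
        cix = np.clip(((xs - bathy.origin_easting) / bathy.cell_size).astype(int),
                      0, bathy.n_cols - 1)
        ciy = np.clip(((ys - bathy.origin_northing) / bathy.cell_size).astype(int),
                      0, bathy.n_rows - 1)
        depth = -bathy.elevation[ciy, cix] + tide_lv

        all_states.append(pd.DataFrame({
            "turtle_id": f"T{ti:02d}", "timestamp": times,
            "true_easting": xs, "true_northing": ys, "behavior": beh,
            "true_speed_kmh": spd, "true_depth_m": depth,
            "water_temp_C": temp, "is_night": night,
        }))

    states = pd.concat(all_states, ignore_index=True)
    bouts = pd.DataFrame(bout_rows, columns=["turtle_id", "start_time", "end_time"])
    if len(bouts):
        bouts["duration_h"] = ((bouts["end_time"] - bouts["start_time"])
                               / pd.Timedelta(hours=1))
    return states, bouts


def observe(states: pd.DataFrame, config: SimConfig
            ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the GPS observation process over true states.

    Hourly fix attempts succeed with day/night-dependent probability;
    successful fixes carry isotropic Gaussian position error with the
    configured 50% circular error (6 m).  Corruptions: with ``p_hdop_fail``
    a fix gets HDOP > 25 and a gross position error; with ``p_duplicate``
    a second fix follows within 10 min (the earlier of the pair is the
    poorer solution); with ``p_outlier`` an extra fix displaced by several
    km (implying > 4 km/h) is inserted between attempts.

    Returns ``(fixes, truth)`` where truth links each fix id to its true
    position, behavior and corruption label — for tests only.
    """
    rng = np.random.default_rng([config.seed % (2**31), 7919])
    sigma_xy = config.gps_cep50_m / np.sqrt(2.0 * np.log(2.0))
    step_h = config.step_min / 60.0

    attempts = pd.date_range(config.start, config.end, freq="h", inclusive="left")
    night_att = _is_night_array(config, attempts)
    p_att = np.where(night_att, config.night_detection_prob,
                     config.day_detection_prob)

    fix_rows = []
    truth_rows = []
    for tid, sub in states.groupby("turtle_id", sort=False):
        sub = sub.reset_index(drop=True)
        t0 = pd.Timestamp(sub["timestamp"].iloc[0])
        idx_of = np.round((attempts - t0) / pd.Timedelta(hours=1) / step_h).astype(int)
        ok = (idx_of >= 0) & (idx_of < len(sub))

        success = rng.random(len(attempts)) < p_att
        for ai in np.nonzero(success & ok)[0]:
            si = idx_of[ai]
            tx = sub["true_easting"].iloc[si]
            ty = sub["true_northing"].iloc[si]
            records = [(attempts[ai], 0.0, "clean")]

            u = rng.random()
            if u < config.p_hdop_fail:
                records = [(attempts[ai], config.hdop_fail_error_m, "hdop")]
            elif u < config.p_hdop_fail + config.p_duplicate:
                dt2 = int(rng.integers(60, 9 * 60))
                records = [(attempts[ai], 2.0 * sigma_xy, "duplicate_first"),
                           (attempts[ai] + pd.Timedelta(seconds=dt2), 0.0,
                            "duplicate_second")]
            elif u < config.p_hdop_fail + config.p_duplicate + config.p_outlier:
                dt3 = int(rng.integers(11 * 60, 49 * 60))
                records = [(attempts[ai], 0.0, "clean"),
                           (attempts[ai] + pd.Timedelta(seconds=dt3),
                            config.outlier_offset_m, "outlier")]

            for ts, extra_err, label in records:
                ex = tx + rng.normal(0.0, sigma_xy)
                ey = ty + rng.normal(0.0, sigma_xy)
                if label == "hdop":
                    ang = rng.uniform(0, 2 * np.pi)
                    r = rng.exponential(extra_err)
                    ex += r * np.sin(ang)
                    ey += r * np.cos(ang)
                    hdop = rng.uniform(26.0, 60.0)
                elif label == "duplicate_first":
                    ex += rng.normal(0.0, extra_err)
                    ey += rng.normal(0.0, extra_err)
                    hdop = rng.uniform(5.0, 20.0)
                elif label == "outlier":
                    ang = rng.uniform(0, 2 * np.pi)
                    ex += extra_err * np.sin(ang)
                    ey += extra_err * np.cos(ang)
                    hdop = rng.uniform(0.8, 2.5)
                else:
                    hdop = rng.uniform(0.8, 2.5)
                fix_rows.append({
                    "turtle_id": tid, "timestamp": ts,
                    "easting_obs": ex, "northing_obs": ey, "hdop": hdop,
                    "water_temp_C": sub["water_temp_C"].iloc[si]
                    + rng.normal(0.0, 0.3),
                })
                truth_rows.append({
                    "turtle_id": tid, "timestamp": ts,
                    "true_easting": tx, "true_northing": ty,
                    "behavior": sub["behavior"].iloc[si],
                    "true_depth_m": sub["true_depth_m"].iloc[si],
                    "corruption": label,
                })

    fixes = pd.DataFrame(fix_rows).sort_values(
        ["turtle_id", "timestamp"], kind="stable").reset_index(drop=True)
    truth = pd.DataFrame(truth_rows).sort_values(
        ["turtle_id", "timestamp"], kind="stable").reset_index(drop=True)
    fixes.insert(0, "fix_id", np.arange(len(fixes)))
    truth.insert(0, "fix_id", fixes["fix_id"].to_numpy())

    lon, lat = utm_to_geographic(fixes["easting_obs"].to_numpy(),
                                 fixes["northing_obs"].to_numpy())
    fixes["lon"] = lon
    fixes["lat"] = lat
    fixes = fixes.drop(columns=["easting_obs", "northing_obs"])
    return fixes, truth


def simulate(config: SimConfig):
    """Full synthetic study: bathymetry, tide, tracks, observed fixes.

    Returns a dict with ``bathymetry``, ``tide``, ``bay_polygon``,
    ``states``, ``drift_bouts``, ``fixes`` and ``truth``.
    """
    bathy = make_bathymetry(config)
    tide = make_tide(config)
    states, bouts = simulate_tracks(config, bathy, tide)
    fixes, truth = observe(states, config)
    return {"bathymetry": bathy, "tide": tide, "bay_polygon": bay_polygon(config),
            "states": states, "drift_bouts": bouts, "fixes": fixes, "truth": truth}
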