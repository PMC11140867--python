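# driftline

Movement analysis for hourly GPS telemetry of coastal foraging sea
turtles — and a synthetic world to validate every step of it.

Juvenile and adult loggerhead turtles foraging in shallow Gulf-coast bays
carry GPS tags that attempt one fix per hour.  Turning those fixes into
ecology requires a chain of careful steps: discarding poor-quality fixes,
joining the rest into travel lines, correcting water depths for tide
stage, splitting behavior by sunrise and sunset, estimating home ranges
from slow movements, and recognizing multi-day bouts of passive
"drifting".  `driftline` implements that chain as a tested Python
library for anyone working with hourly animal telemetry in shallow
coastal systems.

## What it computes

- **QC filtering** — HDOP > 25 discarded; duplicate fixes within 10 min
  collapsed onto the later, updated solution; fixes implying > 4 km/h
  removed iteratively against the last retained fix.  Exact per-turtle
  count bookkeeping, plus daily and hour-of-day reception rates against
  the 24-attempts/day schedule.
- **Travel lines** — segments between successive fixes with length
  (projected meters, UTM 16N via an internal Krüger-series transverse
  Mercator), duration, speed, heading, and signed turn angle; attributes
  assigned to the destination fix.
- **Depth & diel context** — bilinear DEM sampling plus tide-gauge
  correction (`depth = −elevation + water level`, positive down); NOAA
  solar equations give sunrise/sunset and a day/night split with a ±2 h
  crepuscular overlay.
- **Home ranges** — Gaussian kernel density (σ = 150 m) over travel
  lines filtered to speed ≤ 0.08 km/h, length ≤ 320 m, Δt ≤ 4 h; 50% and
  90% mass isopleths, diel-stratified ranges, and multi-turtle overlap
  tables on a common grid.
- **Drifting** — episodes of ≥ 12 h of slow (≤ 0.06 km/h), nearly
  straight (< 20° turning), well-received (≥ 50%) movement, with
  per-turtle prevalence and temperature-band summaries.
- **Summary statistics** — stratified speed medians with empirical 95%
  ranges, a per-turtle-intercept temperature–speed slope, and a
  per-turtle summary table.
- **Synthetic world** — bathymetry, tides, seasonal temperature,
  behavior-switching turtle tracks (deep residents, nocturnal
  tide-gated shoal movers, cold-triggered gulf excursions,
  temperature-dependent drifting) and a corrupting GPS observation
  process, with ground truth emitted for validation.

See `docs/methods.md` for the models and conventions in detail.

## A worked example

```python
import driftline as dl

config = dl.SimConfig(seed=1, n_turtles=3,
                      start_time="2019-01-01", end_time="2019-02-01")
world = dl.simulate(config)

fixes = dl.project_fixes(world["fixes"])   # lon/lat -> UTM meters
kept, report = dl.apply_filters(fixes)
print(report.to_dict())
```

prints

```
{'n_input': 1676, 'n_hdop_removed': 29, 'n_duplicate_removed': 91,
 'n_speed_removed': 10, 'n_retained': 1546}
```

— of 1676 successful fix attempts in a simulated January, 29 had poor
satellite geometry, 91 were near-duplicate retransmissions, and 10
implied impossible speeds; 1546 survive for analysis.  Continuing,

```python
segments = dl.build_segments(kept)
episodes = dl.detect_drift(segments, kept)
per_turtle, bands = dl.drift_summary(episodes, kept)
print(per_turtle.round(1))
```

```
  turtle_id  n_episodes  drift_hours  tracked_hours  percent_time
0       T00          11        345.9          740.0          46.7
1       T01           1         59.0          740.0           8.0
2       T02           5        117.0          734.0          15.9
```

All three turtles drifted — long, slow, straight excursions with good
GPS reception — but prevalence varies widely in the cold month, from
almost half of one resident's time to 8% for the turtle that left for
the gulf.  The
`examples/` directory holds four narrative scripts covering filtering
and reception, home ranges and overlap, drifting and temperature, and
depth/diel speed stratification; each prints the numbers it computes and
a line on what they mean.

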