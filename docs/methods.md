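# Methods

`driftline` analyses hourly GPS telemetry of coastal foraging sea turtles.
This note records the models and procedures it implements, the choices
made where a convention had to be fixed, and what the synthetic-world
validation does and does not demonstrate.

## Coordinate handling

Fixes arrive as WGS84 longitude/latitude and are projected to UTM zone
16N (the study region, a Gulf-coast bay near 29.8°N) so that distances
and areas are in meters.  The transverse Mercator mapping is implemented
directly with Krüger's series in the conformal coordinates, truncated at
n⁶; within a UTM zone this is accurate to well under a millimeter, and
round-trip error is below 1 cm in tests.  The test suite cross-checks it
against an independently coded Snyder-series projection, an adaptive
quadrature of the meridian arc, and frozen geodesic destination points
computed with Karney's algorithm (R `geosphere`).  Segment lengths are
Euclidean in the projected plane; at bay scale (tens of km) the
difference from geodesic lengths is within the local scale-factor
deviation of a few parts in 10⁴ and is ignored.

## Quality filtering

Three fix-level filters run as a fixed pipeline with exact count
bookkeeping:

1. **HDOP** — fixes with horizontal dilution of precision strictly above
   25 are discarded; missing HDOP is retained (and counted).
2. **Duplicates** — when two fixes from one tag arrive within 10 minutes
   the earlier one is discarded (the later fix is the tag's updated,
   higher-quality solution).  A left-to-right scan collapses chains of
   near-simultaneous fixes onto the final member.
3. **Speed** — fixes whose travel speed from the previous *retained* fix
   exceeds 4 km/h are removed in a forward walk, so removing an outlier
   re-exposes its successor to a fair test (equivalent to
   remove-first-offender-and-recompute until stable).  A single-pass
   variant is kept for sensitivity analysis; the iterative mode is the
   default because a single gross outlier otherwise drags its innocent
   neighbor out with it.

Duplicate removal precedes the speed filter deliberately: near-zero time
separations otherwise produce absurd apparent speeds.  All thresholds use
strict inequalities (`> 25`, `< 10 min`, `> 4 km/h`).

## Travel lines, depth, diel class

Successive retained fixes become directed segments with length, duration,
speed, heading (degrees clockwise from grid north) and signed turn angle
wrapped to (−180°, 180°]; each segment's attributes attach to its
destination fix (second-point attribution), and a turtle's first segment
has an undefined (NaN) turn angle rather than zero.  Segments spanning
more than 4 h are flagged as gaps; the home-range selection excludes
them, other analyses keep them.

Depth at a fix is `−elevation + water_level(t)` (positive down): the DEM
elevation is sampled bilinearly from the four surrounding cell centers
(nodata neighbors fall back to the nearest valid cell, flagged), and the
tide gauge series is joined by nearest hour within 30 minutes — beyond
that the depth is flagged missing rather than extrapolated.

Sunrise and sunset come from the NOAA solar-position equations (zenith
90.833°, i.e. standard refraction plus the solar half-diameter), refined
once by re-evaluating the solar position at the first-guess event time;
agreement with an independent almanac ephemeris is a few seconds over a
year at the study latitude.  Days are split at sunrise/sunset; a
crepuscular overlay marks the closed ±2 h windows around each event, so
both the 2-way and the 3-way partitions stay available.  Each turtle-day
uses that day's mean fix position for the solar geometry; tracks move far
less than 0.2°/day, keeping event-time sensitivity under a minute.

## Home ranges

The utilization surface is a Gaussian kernel density (σ = 150 m) over
*travel lines*: segments filtered to speed ≤ 0.08 km/h, length ≤ 320 m
and duration ≤ 4 h are discretized into points at most half a grid cell
apart, each carrying its share of segment length, and smoothed on a 25 m
grid (σ/6).  Cell values are meters of track per m², so the surface
integrates to total selected track length; no edge correction is applied
and the grid is padded 4σ beyond the data, keeping mass loss below 0.5%
(in practice ~10⁻¹⁴ relative).  The p% home range is the smallest-area
cell set holding p% of the surface mass, found by ranking cells by
density and accumulating; ties at the threshold level are included, which
guarantees nestedness of the 50% inside the 90% isopleth.  A point-like
track reproduces the closed-form Gaussian disk areas
(πσ²·2ln2 ≈ 0.098 km² at 50%, πσ²·2ln10 ≈ 0.326 km² at 90%) within a
fraction of a percent, and halving the cell size moves areas by well
under 3%.  For multi-turtle overlap, surfaces are built on one shared
grid and cells are counted by how many turtles' isopleths contain them.
When a bay/water polygon is supplied, masks can be clipped to it before
area computation.

## Drifting detection

A drifting episode is a run of segments satisfying four criteria: speed
≤ 0.06 km/h; turning angle magnitude < 20°; total duration ≥ 12 h
(episodes over 5 days are flagged, not truncated); and GPS reception ≥
50% of the hourly attempt schedule across the run.  Runs tolerate
non-qualifying interruptions up to 2 h (hourly fixes drop out; the
reception criterion itself presumes missing fixes inside episodes).

The turning-angle test is evaluated on **window-coarsened headings** by
default: the heading of the net displacement over the trailing 2 h is
compared with that of the preceding, non-overlapping 2 h window.  The
reason is statistical, and worth stating precisely.  At drift speeds the
hourly displacement is at most 60 m, while each fix carries ~6 m (50%
circular) position error; per-step turn angles then have a noise standard
deviation near 15°, so a strict per-step |turn| < 20° test rejects a
fifth of genuinely straight drift segments and shatters episodes — no
parameterization fixes this, because pushing displacement high enough to
quiet the angle noise (≳70 m/h) violates the 0.06 km/h speed ceiling.
Over 2 h windows the angular noise drops to ~5°, while meandering
resident movement still decorrelates between adjacent windows and is
rejected.  The strict per-step test and a run-median variant remain
available (`angle_mode`), since a visual-review judgment of "small
turning angles" admits more than one defensible algorithmic reading.

Summaries report per-turtle episode counts and percent of tracked time
drifting, plus the fraction of time drifting within water-temperature
bands (< 16 °C, 16–28 °C, > 28 °C) computed from fix temperatures.

## Descriptive statistics

Speed summaries are the median and the empirical 95% range (2.5th–97.5th
percentiles, linear interpolation, one value per segment) per stratum:
bay vs. gulf, tide-corrected destination depth above/below 6 m, and diel
class.  The temperature–speed relationship is a fixed-effects least
squares fit — speed on temperature with a separate intercept per turtle —
which estimates the same slope as a random-intercept mixed model on
balanced data but makes no claim to its inference; it is a descriptive
stand-in, not a re-fit.

## The synthetic world

The generator exists so every stage can be validated against known
ground truth; its defaults encode the study conditions the analysis
assumes.

**Physical setting.**  A 10 × 12 km bay in UTM 16N with a 2.5 km shoal
band (1 m deep) along the eastern shore cut by three 400 m channels
(6 m), a 6 m basin, and a 10 m gulf strip west of the bay mouth; a 0.3 m
semidiurnal tide (12.42 h); water temperature a seasonal sinusoid from
14 °C (winter) to 30 °C (late July peak).

**Behavior.**  Turtles follow one of two archetypes.  *Deep residents*
perform a correlated random walk in the basin (active speed lognormal,
median 0.08 km/h, σ_log 0.7; heading σ 60° per 6-min step) and never
enter water shallower than 1.5 m.  *Diel movers* live near the shoal
edge and commute onto a fixed foraging patch at night when the tide
stands above mean sea level, leaving at dawn or when the tide falls —
so shoal occupancy is nocturnal and concentrated at high tide by
construction.  Commutes are directed transits (median 0.45 km/h).
Gulf-capable turtles leave the bay after 72 h below 16 °C and return
weeks later, moving faster outside (median 0.24 km/h).  Active swimming
speeds scale by +2% per °C around the seasonal mean, the ectotherm
physiology the speed–temperature analysis looks for; note that the *raw*
fixed-effect slope on simulated data is still composition-confounded
(cold months bring fast gulf excursions and longer foraging nights),
which is itself a faithful property of such data.

**Drifting.**  Bouts initiate from resident movement with a hazard set so
the stationary drifting time-fraction interpolates linearly between
36.2% at 16 °C and 4.7% at 28 °C; durations are 12 h plus an exponential
tail capped at 5 days.  A bout is bracketed by directed transits — a 4 h
swim out to the drift line and a 3 h return — with heading continuity
into the passive phase; the drift itself is nearly straight (heading σ
0.6° per step) at lognormal median 0.045 km/h, follows along-bay
directions, and curves away from shores at no more than ~4°/h rather
than reflecting, since a passively transported animal cannot reverse
instantaneously.  Ground-truth bout intervals (the passive phase only)
are emitted in a sidecar table.  The realized drifting fraction in cold
water comes out below the 36% hazard anchor (roughly a quarter of cold
time) because bouts only initiate from resident phases and entry/exit
transits do not count as drifting; the monotone temperature dependence —
the property the analysis must recover — is unaffected.

**Observation.**  Hourly fix attempts succeed with probability 0.9 at
night and 0.45 by day by default (within the reported 20–80% daytime
deficit); successful fixes get isotropic Gaussian error with 6 m median
radius.  Corruptions mirror the QC filters' targets: with small
probabilities a fix carries HDOP > 25 plus a gross error, a second fix
follows within 10 minutes (the earlier being the poorer solution), or an
extra fix displaced by ~6 km (implying > 4 km/h) is inserted.  Truth
tables keyed by fix id record true positions, behavior and corruption
labels; analysis code never reads them — only tests and validation do.

**What passing does and does not show.**  The generator reproduces the
statistical structure the pipeline assumes — diel detection bias,
tide-gated habitat access, temperature-dependent drifting, GPS error of
the right scale — but not hydrodynamics, prey fields, GNSS error
correlation, or tag duty-cycle effects.  Recovery results therefore
validate the algorithms and their noise handling, not field performance
on any particular real deployment.

## Validation experiments

`driftline.validation` (exercised by `tests/test_acceptance.py` and
`scripts/acceptance.py`) measures, end to end:

- closed-form isopleth areas and kernel mass conservation / grid
  convergence (~1000-segment simulated tracks);
- exact QC filter counts on a hand-enumerable fixture, cross-checked in
  tests against brute-force reference scans;
- solar event times over a year against an independently coded USNO
  low-precision almanac ephemeris (observed: a few seconds; bound 2 min);
- drift-bout recovery on 10 turtles × 90 winter days at 0.7/0.9
  detection: the union of detected episodes must reproduce each ≥ 14 h
  truth bout's *observable* boundaries — its first and last received fix
  — within 2 h.  The observable extent is the right reference because,
  at 0.7 daytime detection, ~9% of bouts have no fix at all within 2 h of
  one of their true boundaries; no detector can place a boundary across
  that reception gap, and the check aims at the detector, not the radio
  link.  Measured recovery is 92–97% across seeds with ≤ ~1% false
  episodes;
- recovery of the diel/tide structure (nocturnal 90% ranges larger than
  diurnal for every mover; Spearman correlation of night shoal occupancy
  with tide level ~0.3–0.45) and of the temperature–drift monotonicity
  (cold-water drift fraction many times the warm-water fraction) over a
  simulated year.

Problem sizes (90-day and 1-year simulations at a 6-min internal step,
25 m kernel grids) keep the full validation under a minute of compute;
they are the sizes at which the measured properties are stable across
seeds.

## Known limitations

- The bay geometry is rectangular with an idealized shoal band; shoreline
  clipping of home ranges is supported but the synthetic coast is
  trivial.
- Depth stratification uses the destination-fix depth (consistent with
  second-point attribution); segment-mean depth is not offered.
- The temperature–speed slope is descriptive; no mixed-model inference
  (standard errors under within-turtle autocorrelation) is attempted.
- The drifting detector's gap tolerance (2 h) and angle window (2 h) are
  operational constants exposed as parameters; sensitivity to them is
  easy to explore but not automated.
- Tide handling assumes a single gauge represents the whole bay; no
  spatial tide propagation.
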