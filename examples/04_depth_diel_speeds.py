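"""Tide-corrected depths, diel classes and stratified travel speeds.

Each fix gets a water depth from the bathymetry DEM corrected for tide
stage; each travel segment gets a day/night/crepuscular label from NOAA
solar geometry.  Speeds are then summarized per stratum (bay vs gulf,
depth class, diel class) as the median with an empirical 95% range, and
the temperature effect on speed is a fixed-effects least-squares slope
with one intercept per turtle.
"""

import driftline as dl

config = dl.SimConfig(seed=9, n_turtles=4,
                      start_time="2019-01-01", end_time="2019-07-01")
world = dl.simulate(config)
fixes = dl.project_fixes(world["fixes"])
kept, _ = dl.apply_filters(fixes)

segments = dl.build_segments(kept)
segments = dl.assign_depth(segments, world["bathymetry"], world["tide"],
                           easting_col="end_easting",
                           northing_col="end_northing")
segments = dl.classify_bay(segments, world["bay_polygon"],
                           easting_col="end_easting",
                           northing_col="end_northing")
segments = dl.annotate_diel(segments)

table = dl.speed_by_stratum(segments, dl.standard_strata(segments))
print("segment speeds (km/h) by stratum - median [2.5%, 97.5%]:")
for _, r in table.iterrows():
    print(f"  {r['stratum']:18s} {r['median_kmh']:.3f} "
          f"[{r['q2.5_kmh']:.3f}, {r['q97.5_kmh']:.3f}]  n={r['n_segments']}")

fit = dl.temp_speed_slope(segments)
print(f"\nspeed-temperature slope: {fit['slope_kmh_per_C']:+.4f} km/h per °C "
      f"(SE {fit['se']:.4f}, n={fit['n_segments']})")
print("\nTurtles move faster over the shallow shoals; the nocturnal shoal "
      "commute makes night speeds higher in this simulation.  The raw "
      "temperature slope is near zero: the physiological speed-up in warm "
      "water is offset by composition (cold months bring fast gulf "
      "excursions and long foraging nights), a reminder that this slope "
      "mixes behaviour and physiology unless behaviour is controlled for.")
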