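"""Line-kernel home ranges, diel contrast and between-turtle overlap.

Travel lines (successive filtered fixes) restricted to slow, short steps
are smoothed with a 150 m Gaussian kernel; the 50% and 90% isopleths of
the resulting utilization surface are each turtle's core area and home
range.  Night and day ranges are computed separately, and a common grid
lets the overlap table count cells shared between turtles.
"""

import driftline as dl

config = dl.SimConfig(seed=3, n_turtles=4,
                      archetypes=["diel_mover", "diel_mover",
                                  "deep_resident", "diel_mover"],
                      start_time="2019-01-01", end_time="2019-03-01")
world = dl.simulate(config)
fixes = dl.project_fixes(world["fixes"])
kept, _ = dl.apply_filters(fixes)
segments = dl.annotate_diel(dl.build_segments(kept))

# one shared grid so surfaces can be overlaid
sel = dl.select_hr_segments(segments)
bounds = (sel["end_easting"].min(), sel["end_northing"].min(),
          sel["end_easting"].max(), sel["end_northing"].max())

hr90 = []
print(f"{'turtle':8s} {'50% km2':>8s} {'90% km2':>8s} {'night/day 90%':>14s}")
for tid, sub in sel.groupby("turtle_id"):
    surface = dl.line_kde(sub, bounds=bounds)
    h50 = dl.isopleth(surface, 50, turtle_id=tid)
    h90 = dl.isopleth(surface, 90, turtle_id=tid)
    hr90.append(h90)
    night = dl.diel_homerange(segments[segments.turtle_id == tid], "night",
                              90, turtle_id=tid, bounds=bounds)
    day = dl.diel_homerange(segments[segments.turtle_id == tid], "day",
                            90, turtle_id=tid, bounds=bounds)
    ratio = (night.area_km2 / day.area_km2
             if night is not None and day is not None else float("nan"))
    print(f"{tid:8s} {h50.area_km2:8.2f} {h90.area_km2:8.2f} {ratio:14.2f}")

print("\n90% home-range overlap (cells shared by k turtles):")
print(dl.overlap_table(hr90).to_string(index=False))
print("\nMovers that forage across the shoal at night have larger nocturnal "
      "ranges; most of the joint area belongs to a single turtle.")
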