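"""Detect multi-day "drifting" episodes and relate them to temperature.

Drifting = at least 12 h of continuous slow (<= 0.06 km/h), nearly
straight movement with good GPS reception - a turtle riding surface
currents instead of swimming.  The detector scans the travel segments and
the summary relates time spent drifting to water temperature.
"""

import driftline as dl

config = dl.SimConfig(seed=5, n_turtles=4,
                      archetypes=["deep_resident", "diel_mover"] * 2,
                      start_time="2019-01-01", end_time="2020-01-01")
world = dl.simulate(config)
fixes = dl.project_fixes(world["fixes"])
kept, _ = dl.apply_filters(fixes)
segments = dl.build_segments(kept)

episodes = dl.detect_drift(segments, kept)
per_turtle, bands = dl.drift_summary(episodes, kept)

print("per-turtle drifting over one simulated year:")
print(per_turtle.round(1).to_string(index=False))

print("\nfraction of time drifting by water temperature band:")
print(bands.round(3).to_string(index=False))

frame = dl.episodes_frame(episodes)
print(f"\nlongest episode: {frame['duration_h'].max():.0f} h at "
      f"{frame.loc[frame['duration_h'].idxmax(), 'mean_speed_kmh']:.3f} km/h")
print("\nDrifting concentrates in cold water: the sub-16 °C drift fraction "
      "is many times the warm-water (>28 °C) fraction.")
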