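import numpy as np
import pandas as pd
import pytest

import driftline as dl

STUDY_LAT = 29.75
STUDY_LON = -85.35


@pytest.fixture(scope="session")
def small_world():
    """Three turtles, three winter weeks: exercises drift + diel movement."""
    cfg = dl.SimConfig(seed=11, n_turtles=3,
                       start_time="2019-01-01", end_time="2019-01-22")
    return dl.simulate(cfg)


@pytest.fixture(scope="session")
def small_pipeline(small_world):
    """QC-filtered, projected, attributed segments for the small world."""
    world = small_world
    fixes = dl.project_fixes(world["fixes"])
    kept, report = dl.apply_filters(fixes)
    segments = dl.build_segments(kept)
    segments = dl.assign_depth(segments, world["bathymetry"], world["tide"],
                               easting_col="end_easting",
                               northing_col="end_northing")
    segments = dl.classify_bay(segments, world["bay_polygon"],
                               easting_col="end_easting",
                               northing_col="end_northing")
    segments = dl.annotate_diel(segments)
    return {**world, "fixes": kept, "report": report, "segments": segments}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_fixes(turtle_id, times_min, xy, hdop=1.0, t0="2020-06-01"):
    """Small projected fix table from minute offsets and metric coords."""
    base = pd.Timestamp(t0, tz="UTC")
    xy = np.asarray(xy, float)
    n = len(times_min)
    lon, lat = dl.telemetry_io.unproject(xy[:, 0], xy[:, 1])
    return pd.DataFrame({
        "fix_id": np.arange(n),
        "turtle_id": turtle_id,
        "timestamp": [base + pd.Timedelta(minutes=float(m)) for m in times_min],
        "lon": np.atleast_1d(lon), "lat": np.atleast_1d(lat),
        "hdop": np.broadcast_to(np.asarray(hdop, float), n).copy(),
        "water_temp_C": np.nan,
        "easting": xy[:, 0], "northing": xy[:, 1],
    })
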