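"""Segment construction, depth correction, bay classification."""

import numpy as np
import pandas as pd
import pytest

import driftline as dl
from driftline.geodesy import wrap_angle_deg
from driftline.telemetry_io import BathymetryGrid, TideSeries

from _oracles import ray_casting_inside
from conftest import make_fixes
from shapely.geometry import Polygon


class TestBuildSegments:
    def test_eastward_kilometer_in_one_hour(self):
        fx = make_fixes("A", [0, 60], [(0, 0), (1000, 0)])
        seg = dl.build_segments(fx)
        row = seg.iloc[0]
        assert row["length_m"] == pytest.approx(1000.0)
        assert row["speed_kmh"] == pytest.approx(1.0)
        assert row["heading_deg"] == pytest.approx(90.0)
        assert np.isnan(row["turn_angle_deg"])  # first segment: undefined

    def test_collinear_track_turns_zero(self):
        fx = make_fixes("A", [0, 60, 120], [(0, 0), (1000, 0), (2000, 0)])
        seg = dl.build_segments(fx)
        assert seg["turn_angle_deg"].iloc[1] == pytest.approx(0.0)

    def test_heading_wrap_90_to_350_gives_minus_100(self):
        fx = make_fixes("A", [0, 60, 120],
                        [(0.0, 0.0), (1000.0, 0.0),
                         (1000.0 + 1000 * np.sin(np.radians(350)),
                          1000 * np.cos(np.radians(350)))])
        seg = dl.build_segments(fx)
        assert seg["heading_deg"].iloc[1] == pytest.approx(350.0)
        assert seg["turn_angle_deg"].iloc[1] == pytest.approx(-100.0)

    def test_turn_angles_match_exhaustive_wrap_oracle(self):
        h = np.arange(0.0, 360.0, 1.0)
        for h1 in (0.0, 37.0, 179.0, 180.0, 271.0):
            diff = wrap_angle_deg(h - h1)
            # brute-force minimal signed difference
            cand = np.stack([h - h1, h - h1 + 360.0, h - h1 - 360.0])
            ref = cand[np.argmin(np.abs(cand), axis=0), np.arange(len(h))]
            ref[ref == -180.0] = 180.0
            np.testing.assert_allclose(diff, ref, atol=1e-12)

    def test_segment_count_and_speed_identity(self, small_pipeline):
        fixes = small_pipeline["fixes"]
        segs = small_pipeline["segments"]
        per_fix = fixes.groupby("turtle_id").size()
        per_seg = segs.groupby("turtle_id").size()
        for tid in per_fix.index:
            assert per_seg[tid] == per_fix[tid] - 1
        np.testing.assert_allclose(
            segs["speed_kmh"],
            (segs["length_m"] / 1000.0) / segs["duration_h"], rtol=1e-12)
        # the QC speed filter left nothing above its limit
        assert segs["speed_kmh"].max() <= 4.0

    def test_duplicate_timestamps_rejected_with_ids(self):
        fx = make_fixes("A", [0, 0], [(0, 0), (10, 0)])
        with pytest.raises(ValueError, match="non-increasing"):
            dl.build_segments(fx)

    def test_gap_flagging(self):
        fx = make_fixes("A", [0, 60, 60 + 5 * 60], [(0, 0), (10, 0), (20, 0)])
        seg = dl.build_segments(fx)
        assert list(seg["is_gap"]) == [False, True]


class TestAssignDepth:
    def make_world(self, elev):
        grid = BathymetryGrid(0.0, 0.0, 100.0, np.full((4, 4), elev))
        ts = pd.date_range("2020-06-01", periods=24, freq="h", tz="UTC")
        return grid, ts

    def test_sign_convention_deep(self):
        grid, ts = self.make_world(-5.0)
        tide = TideSeries(ts, np.full(24, 0.3))
        fx = make_fixes("A", [0], [(200, 200)])
        out = dl.assign_depth(fx, grid, tide)
        assert out["depth_m"].iloc[0] == pytest.approx(5.3)

    def test_sign_convention_shallow_low_tide(self):
        grid, ts = self.make_world(-1.0)
        tide = TideSeries(ts, np.full(24, -0.3))
        fx = make_fixes("A", [0], [(200, 200)])
        out = dl.assign_depth(fx, grid, tide)
        assert out["depth_m"].iloc[0] == pytest.approx(0.7)

    def test_missing_tide_cover_flags_depth(self):
        grid, ts = self.make_world(-5.0)
        tide = TideSeries(ts, np.zeros(24))
        fx = make_fixes("A", [0], [(200, 200)], t0="2021-01-01")
        out = dl.assign_depth(fx, grid, tide)
        assert np.isnan(out["depth_m"].iloc[0])
        assert out["depth_flag"].iloc[0] == "no_tide_cover"

    def test_synthetic_depths_recover_ground_truth(self, small_pipeline):
        """Assigned depths match the generator's true depths up to GPS
        position error moving a fix across a cell boundary."""
        fixes = dl.assign_depth(small_pipeline["fixes"],
                                small_pipeline["bathymetry"],
                                small_pipeline["tide"])
        truth = small_pipeline["truth"].set_index("fix_id")
        merged = fixes.join(truth[["true_depth_m", "corruption"]], on="fix_id")
        clean = merged[(merged["corruption"] == "clean")
                       & (merged["depth_flag"] == "ok")]
        err = (clean["depth_m"] - clean["true_depth_m"]).abs()
        # most fixes sit inside one bathymetry cell: median error is tiny,
        # and large errors are confined to shoal-edge/channel boundaries
        assert err.median() < 0.2
        assert (err < 0.5).mean() > 0.8


class TestClassifyBay:
    def test_centroid_inside_and_offshore_outside(self, small_pipeline):
        poly = small_pipeline["bay_polygon"]
        c = poly.centroid
        fx = make_fixes("A", [0, 60],
                        [(c.x, c.y), (poly.bounds[0] - 10_000.0, c.y)])
        out = dl.classify_bay(fx, poly)
        assert list(out["in_bay"]) == [True, False]

    def test_boundary_counts_as_inside(self, small_pipeline):
        poly = small_pipeline["bay_polygon"]
        x0, y0, x1, y1 = poly.bounds
        fx = make_fixes("A", [0], [(x0, (y0 + y1) / 2)])
        assert dl.classify_bay(fx, poly)["in_bay"].iloc[0]

    def test_agrees_with_ray_casting_oracle(self, rng):
        poly_xy = np.array([(0, 0), (4000, 500), (5000, 3000), (2500, 4500),
                            (-500, 3000)], dtype=float)
        poly = Polygon(poly_xy)
        pts = np.column_stack([rng.uniform(-1000, 6000, 500),
                               rng.uniform(-1000, 5500, 500)])
        fx = make_fixes("A", np.arange(500) * 60, pts)
        out = dl.classify_bay(fx, poly)
        ref = [ray_casting_inside(poly_xy, px, py) for px, py in pts]
        assert list(out["in_bay"]) == ref

    def test_invalid_polygon_rejected(self):
        bad = Polygon([(0, 0), (2, 2), (2, 0), (0, 2)])  # self-intersecting
        fx = make_fixes("A", [0], [(1, 1)])
        with pytest.raises(ValueError, match="polygon"):
            dl.classify_bay(fx, bad)
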