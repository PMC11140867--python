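"""Line-KDE surfaces, percentile isopleths, overlap, diel ranges."""

import numpy as np
import pandas as pd
import pytest

import driftline as dl


def seg_frame(coords, lengths=None):
    coords = np.asarray(coords, float)
    L = (np.hypot(coords[:, 2] - coords[:, 0], coords[:, 3] - coords[:, 1])
         if lengths is None else np.asarray(lengths, float))
    return pd.DataFrame({"start_easting": coords[:, 0],
                         "start_northing": coords[:, 1],
                         "end_easting": coords[:, 2],
                         "end_northing": coords[:, 3],
                         "length_m": L})


@pytest.fixture(scope="module")
def random_track_segments():
    rng = np.random.default_rng(7)
    pts = np.cumsum(rng.normal(0, 40, (1001, 2)), axis=0)
    return seg_frame(np.column_stack([pts[:-1], pts[1:]]))


class TestSelectHrSegments:
    def base(self, **kw):
        row = {"speed_kmh": 0.05, "length_m": 100.0, "duration_h": 2.0}
        row.update(kw)
        return pd.DataFrame([row])

    def test_kept_within_all_limits(self):
        assert len(dl.select_hr_segments(self.base())) == 1

    @pytest.mark.parametrize("kw", [
        {"speed_kmh": 0.09}, {"length_m": 321.0}, {"duration_h": 5.0},
    ])
    def test_excluded_beyond_any_limit(self, kw):
        assert len(dl.select_hr_segments(self.base(**kw))) == 0

    def test_boundaries_inclusive(self):
        kept = dl.select_hr_segments(self.base(
            speed_kmh=0.08, length_m=320.0, duration_h=4.0))
        assert len(kept) == 1


class TestLineKde:
    def test_point_like_segment_gives_symmetric_peak(self):
        s = dl.line_kde(seg_frame([[0, 0, 1, 0]]), sigma_m=150, cell_size_m=25)
        iy, ix = np.unravel_index(np.argmax(s.values), s.values.shape)
        x, y = s.cell_centers()
        assert abs(x[ix] - 0.5) < 25 and abs(y[iy]) < 25
        # radial symmetry: values at +-4 cells along each axis agree
        assert s.values[iy, ix + 4] == pytest.approx(s.values[iy, ix - 4], rel=1e-6)
        assert s.values[iy + 4, ix] == pytest.approx(s.values[iy - 4, ix], rel=1e-6)

    def test_mass_conservation(self, random_track_segments):
        s = dl.line_kde(random_track_segments)
        assert abs(s.grid_mass - s.total_mass) / s.total_mass < 0.005

    def test_additivity_of_distant_segments(self):
        a = seg_frame([[0, 0, 320, 0]])
        b = seg_frame([[0, 750, 320, 750]])  # 5 sigma away
        bounds = (-1000, -1000, 1500, 1800)
        sa = dl.line_kde(a, bounds=bounds)
        sb = dl.line_kde(b, bounds=bounds)
        sab = dl.line_kde(pd.concat([a, b], ignore_index=True), bounds=bounds)
        assert np.max(np.abs(sab.values - sa.values - sb.values)) \
            <= 1e-6 * sab.values.max()

    def test_empty_selection_returns_none(self):
        assert dl.line_kde(seg_frame(np.empty((0, 4)))) is None


class TestIsopleth:
    def test_analytic_gaussian_disk_areas(self):
        s = dl.line_kde(seg_frame([[0, 0, 1, 0]]), sigma_m=150, cell_size_m=25)
        for p, mult in ((50, 2 * np.log(2)), (90, 2 * np.log(10))):
            expected = np.pi * 150.0 ** 2 * mult / 1e6
            assert dl.isopleth(s, p).area_km2 == pytest.approx(expected, rel=0.02)

    def test_nestedness_and_monotone_area(self, random_track_segments):
        s = dl.line_kde(random_track_segments)
        prev = None
        for p in (20, 50, 70, 90, 99):
            hr = dl.isopleth(s, p)
            if prev is not None:
                assert not np.any(prev.mask & ~hr.mask)  # subset
                assert prev.area_km2 <= hr.area_km2
            prev = hr

    def test_p100_covers_every_nonzero_cell(self, random_track_segments):
        s = dl.line_kde(random_track_segments)
        hr = dl.isopleth(s, 100)
        assert hr.mask.sum() == (s.values > 0).sum()

    def test_out_of_range_percentile_rejected(self, random_track_segments):
        s = dl.line_kde(random_track_segments)
        with pytest.raises(ValueError):
            dl.isopleth(s, 0.0)
        with pytest.raises(ValueError):
            dl.isopleth(s, 101.0)

    def test_grid_convergence(self, random_track_segments):
        areas = {}
        for cell in (25.0, 12.5):
            s = dl.line_kde(random_track_segments, cell_size_m=cell)
            areas[cell] = (dl.isopleth(s, 50).area_km2,
                           dl.isopleth(s, 90).area_km2)
        for k in range(2):
            rel = abs(areas[12.5][k] - areas[25.0][k]) / areas[25.0][k]
            assert rel < 0.03


class TestOverlap:
    def build(self, offsets, bounds=(-1500, -1500, 4500, 1500)):
        hrs = []
        for i, off in enumerate(offsets):
            s = dl.line_kde(seg_frame([[off, 0, off + 300, 0]]), bounds=bounds)
            hrs.append(dl.isopleth(s, 90, turtle_id=f"T{i}"))
        return hrs

    def test_disjoint_ranges_do_not_overlap(self):
        tab = dl.overlap_table(self.build([0.0, 3000.0]))
        assert tab.loc[tab.n_turtles == 1, "percent_of_union"].iloc[0] \
            == pytest.approx(100.0)
        assert tab.loc[tab.n_turtles == 2, "area_km2"].iloc[0] == 0.0

    def test_identical_ranges_fully_overlap(self):
        tab = dl.overlap_table(self.build([0.0, 0.0]))
        assert tab.loc[tab.n_turtles == 2, "percent_of_union"].iloc[0] \
            == pytest.approx(100.0)
        assert tab.loc[tab.n_turtles == 1, "area_km2"].iloc[0] == 0.0

    def test_three_turtles_match_cell_count_oracle(self):
        hrs = self.build([0.0, 200.0, 2500.0])
        tab = dl.overlap_table(hrs)
        counts = sum(hr.mask.astype(int) for hr in hrs)
        cell_km2 = hrs[0].cell_size ** 2 / 1e6
        for k in (1, 2, 3):
            expected = (counts == k).sum() * cell_km2
            assert tab.loc[tab.n_turtles == k, "area_km2"].iloc[0] \
                == pytest.approx(expected)

    def test_mismatched_grids_rejected(self):
        a = self.build([0.0])[0]
        b = self.build([0.0], bounds=(-1000, -1000, 2000, 1000))[0]
        with pytest.raises(ValueError, match="common grid"):
            dl.overlap_table([a, b])


class TestDielHomerange:
    def test_mover_night_range_exceeds_day_range(self, small_pipeline):
        """Diel movers forage across the shoal at night, so the nocturnal
        90% range covers more area than the diurnal one."""
        segs = small_pipeline["segments"]
        movers = [t for t in segs["turtle_id"].unique()
                  if (small_pipeline["truth"]["behavior"][
                      small_pipeline["truth"]["turtle_id"] == t]
                      == "SHOAL_FORAGE").any()]
        assert movers, "fixture must contain at least one diel mover"
        grew = 0
        for tid in movers:
            sub = segs[segs["turtle_id"] == tid]
            bounds = (sub["end_easting"].min(), sub["end_northing"].min(),
                      sub["end_easting"].max(), sub["end_northing"].max())
            day = dl.diel_homerange(sub, "day", 90, bounds=bounds)
            night = dl.diel_homerange(sub, "night", 90, bounds=bounds)
            if day is not None and night is not None:
                grew += night.area_km2 > day.area_km2
        assert grew >= max(1, len(movers) // 2)

    def test_empty_class_excluded(self):
        segs = seg_frame([[0, 0, 100, 0]])
        segs["diel_base"] = "day"
        segs["speed_kmh"] = 0.05
        segs["duration_h"] = 1.0
        assert dl.diel_homerange(segs, "night", 90) is None
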