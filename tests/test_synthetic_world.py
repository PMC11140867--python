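"""Ground-truth structure of the synthetic world generator."""

import numpy as np
import pandas as pd
import pytest

import driftline as dl
from driftline.synthetic_world import (DRIFT, SHOAL_FORAGE, SimConfig,
                                       make_bathymetry, make_tide,
                                       tide_level, water_temperature)


class TestSimConfigInvariants:
    def test_probabilities_validated(self):
        with pytest.raises(ValueError, match="outside"):
            SimConfig(day_detection_prob=1.4)

    def test_night_detection_must_dominate_day(self):
        with pytest.raises(ValueError, match="night"):
            SimConfig(day_detection_prob=0.9, night_detection_prob=0.5)

    def test_cold_drifting_must_dominate_warm(self):
        with pytest.raises(ValueError, match="cold"):
            SimConfig(drift_prob_cold=0.05, drift_prob_warm=0.3)

    def test_degenerate_extent_rejected_with_sizing_message(self):
        with pytest.raises(ValueError, match="degenerate"):
            SimConfig(bay_width_m=0.0)
        with pytest.raises(ValueError, match="multiple"):
            SimConfig(bay_width_m=10_001.0)


@pytest.fixture(scope="module")
def cfg():
    return SimConfig(seed=0)


@pytest.fixture(scope="module")
def grid(cfg):
    return make_bathymetry(cfg)


class TestBathymetry:

    def test_shoal_band_has_configured_depth(self, cfg, grid):
        shoal = grid.elevation == -cfg.shoal_depth_m
        assert shoal.any()
        depths = -grid.elevation[shoal]
        assert depths.min() == pytest.approx(cfg.shoal_depth_m)

    def test_channels_cut_through_shoal_band(self, cfg, grid):
        shoal_cols = int(cfg.shoal_band_fraction * cfg.bay_width_m
                         / cfg.bathy_cell_m)
        band = grid.elevation[:, grid.n_cols - shoal_cols:]
        assert (band == -cfg.channel_depth_m).any()
        # a channel spans the full band width (navigable to the east edge)
        channel_rows = np.all(band == -cfg.channel_depth_m, axis=1)
        assert channel_rows.sum() >= cfg.n_channels

    def test_water_only_domain(self, grid):
        assert (grid.elevation <= 0).all()

    def test_gulf_strip_is_deepest(self, cfg, grid):
        gulf_cols = int(cfg.gulf_margin_m / cfg.bathy_cell_m)
        assert (grid.elevation[:, :gulf_cols] == -cfg.gulf_depth_m).all()


class TestTide:
    def test_zero_amplitude_is_flat(self):
        tide = make_tide(SimConfig(tide_amplitude_m=0.0))
        assert (tide.water_level_m == 0.0).all()

    def test_extremes_reach_amplitude(self):
        cfg = SimConfig(tide_amplitude_m=0.3)
        tide = make_tide(cfg)
        assert tide.water_level_m.max() == pytest.approx(0.3, abs=0.01)
        assert tide.water_level_m.min() == pytest.approx(-0.3, abs=0.01)

    def test_mean_over_whole_periods_is_msl(self):
        cfg = SimConfig(tide_amplitude_m=0.3)
        # 50 semidiurnal periods = 621 h exactly; fine sampling
        t = pd.date_range(cfg.start, periods=6211, freq="6min")
        levels = tide_level(cfg, t[:-1])
        assert abs(levels.mean()) < 0.005


def test_seasonal_temperature_hits_anchors():
    cfg = SimConfig()
    t = pd.date_range("2019-01-01", "2019-12-31", freq="D", tz="UTC")
    temp = water_temperature(cfg, t)
    assert temp.min() == pytest.approx(cfg.temp_winter_C, abs=0.2)
    assert temp.max() == pytest.approx(cfg.temp_summer_C, abs=0.2)


class TestSimulatedTracks:
    def test_fixed_seed_is_bit_identical(self):
        cfg = dict(seed=31, n_turtles=2, start_time="2019-02-01",
                   end_time="2019-02-08")
        w1 = dl.simulate(SimConfig(**cfg))
        w2 = dl.simulate(SimConfig(**cfg))
        pd.testing.assert_frame_equal(w1["fixes"], w2["fixes"])
        pd.testing.assert_frame_equal(w1["states"], w2["states"])

    def test_deep_resident_never_enters_shallows(self):
        cfg = SimConfig(seed=13, n_turtles=1, archetypes=["deep_resident"],
                        start_time="2019-06-01", end_time="2019-07-01")
        world = dl.simulate(cfg)
        states = world["states"]
        assert (states["true_depth_m"] >= 1.5).all()
        assert not (states["behavior"] == SHOAL_FORAGE).any()

    def test_mover_shoal_time_is_nocturnal(self, small_world):
        states = small_world["states"]
        cfg = SimConfig(seed=11)  # geometry matches the fixture config
        shoal_edge = (cfg.bay_origin_easting + cfg.bay_width_m
                      - cfg.shoal_band_fraction * cfg.bay_width_m)
        on_shoal = states["true_easting"] > shoal_edge
        assert on_shoal.any()
        assert states.loc[on_shoal, "is_night"].mean() >= 0.9

    def test_foraging_only_in_foraging_depths(self, small_world):
        states = small_world["states"]
        forage = states[states["behavior"] == SHOAL_FORAGE]
        assert len(forage) > 0
        assert (forage["true_depth_m"] <= 2.0).all()
        assert forage["is_night"].all()

    def test_drift_bouts_satisfy_duration_bounds(self, small_world):
        bouts = small_world["drift_bouts"]
        cfg = SimConfig(seed=11)
        assert len(bouts) > 0
        assert (bouts["duration_h"] >= cfg.drift_bout_min_h - 0.2).all()
        assert (bouts["duration_h"] <= cfg.drift_bout_max_h + 0.2).all()

    def test_drift_state_is_slow_and_straight(self, small_world):
        states = small_world["states"]
        drifting = states[states["behavior"] == DRIFT]
        assert len(drifting) > 0
        assert drifting["true_speed_kmh"].median() == pytest.approx(0.045,
                                                                    rel=0.1)
        assert (drifting["true_speed_kmh"] < 0.06).mean() > 0.95

    def test_missing_shoal_band_fails_loudly(self):
        cfg = SimConfig(seed=0, n_turtles=1)
        grid = make_bathymetry(cfg)
        grid.elevation[:] = -cfg.channel_depth_m - 1.0
        with pytest.raises(ValueError, match="shoal"):
            dl.synthetic_world.simulate_tracks(cfg, grid)


class TestObservationProcess:
    def test_perfect_detection_gives_hourly_fixes(self):
        cfg = SimConfig(seed=2, n_turtles=1, start_time="2019-06-01",
                        end_time="2019-06-03", day_detection_prob=1.0,
                        night_detection_prob=1.0, p_hdop_fail=0.0,
                        p_duplicate=0.0, p_outlier=0.0)
        world = dl.simulate(cfg)
        assert len(world["fixes"]) == 48

    def test_forced_duplicates_arrive_in_close_pairs(self):
        cfg = SimConfig(seed=2, n_turtles=1, start_time="2019-06-01",
                        end_time="2019-06-03", day_detection_prob=1.0,
                        night_detection_prob=1.0, p_hdop_fail=0.0,
                        p_duplicate=1.0, p_outlier=0.0)
        world = dl.simulate(cfg)
        fixes = world["fixes"]
        assert len(fixes) == 96  # every attempt doubled
        t = pd.to_datetime(fixes["timestamp"], utc=True)
        gaps_min = t.diff().dt.total_seconds().to_numpy()[1::2] / 60.0
        assert (gaps_min < 10.0).all()

    def test_position_error_matches_configured_cep(self, small_world):
        fixes = dl.project_fixes(small_world["fixes"])
        truth = small_world["truth"]
        clean = truth["corruption"] == "clean"
        err = np.hypot(fixes.loc[clean, "easting"] - truth.loc[clean, "true_easting"],
                       fixes.loc[clean, "northing"] - truth.loc[clean, "true_northing"])
        assert np.median(err) == pytest.approx(6.0, rel=0.08)

    def test_corruption_labels_match_filter_targets(self, small_world):
        fixes = dl.project_fixes(small_world["fixes"])
        truth = small_world["truth"]
        hdop_bad = truth.loc[fixes["hdop"] > 25, "corruption"]
        assert (hdop_bad == "hdop").all()
        kept, _ = dl.apply_filters(fixes)
        surviving = truth.set_index("fix_id").loc[kept["fix_id"], "corruption"]
        # outliers and poor duplicates are overwhelmingly removed
        assert (surviving == "outlier").sum() <= 2
        assert (surviving == "hdop").mean() < 0.01

    def test_diel_detection_bias_visible_in_reception(self):
        cfg = SimConfig(seed=17, n_turtles=1, start_time="2019-03-01",
                        end_time="2019-06-09", day_detection_prob=0.3,
                        night_detection_prob=0.9, p_hdop_fail=0.0,
                        p_duplicate=0.0, p_outlier=0.0)
        world = dl.simulate(cfg)
        truth_night = dl.synthetic_world._is_night_array(
            cfg, pd.DatetimeIndex(world["fixes"]["timestamp"]))
        n_attempts = 100 * 24
        n_night_attempts = n_attempts / 2  # ~equinox window
        # crude binomial check: the observed day and night fix counts are
        # far outside each other's 99% intervals
        n_night = truth_night.sum()
        n_day = (~truth_night).sum()
        assert n_night > 1.5 * n_day
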