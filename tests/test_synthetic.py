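"""Synthetic world: scene geometry/determinism, environmental envelopes
and gradients, survey catch mechanics, and sighting placement."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
import shapely
from scipy import stats

from sawdens import (
    EnvConfig,
    EnvFieldSeries,
    EstuaryConfig,
    SurveyDesign,
    TrueModel,
    generate_scene,
    simulate_sightings,
    simulate_survey,
    tweedie_zero_mass,
)
from tests.conftest import SMALL_CONFIG


class TestScene:
    def test_deterministic_given_seed(self, small_scene):
        again = generate_scene(SMALL_CONFIG, seed=42)
        np.testing.assert_array_equal(small_scene.mangrove.data,
                                      again.mangrove.data)
        pd.testing.assert_frame_equal(small_scene.cells, again.cells)

    def test_different_seed_differs(self, small_scene):
        other = generate_scene(SMALL_CONFIG, seed=43)
        assert not np.array_equal(small_scene.mangrove.data,
                                  other.mangrove.data)

    def test_zero_mangrove_fraction(self):
        import dataclasses

        cfg = dataclasses.replace(SMALL_CONFIG, mangrove_fraction=0.0)
        scene = generate_scene(cfg, seed=1)
        assert scene.mangrove.data.sum() == 0
        assert (scene.cells["sum_mnn"] == 0).all()

    def test_negative_distance_iff_outside_river(self, small_scene):
        """Signed distance-to-mouth is negative exactly for cells seaward
        of the river mouths, verified by point-in-polygon against the
        union of river-cell squares."""
        cfg = small_scene.config
        cell = cfg.cell_m
        river_boxes = []
        for _, c in small_scene.cells.iterrows():
            if c["row"] < cfg.mouth_row:
                river_boxes.append(shapely.box(
                    c["x"] - cell / 2, c["y"] - cell / 2,
                    c["x"] + cell / 2, c["y"] + cell / 2))
        river_region = shapely.unary_union(river_boxes)
        inside = shapely.contains_xy(
            river_region, small_scene.cells["x"], small_scene.cells["y"])
        np.testing.assert_array_equal(
            small_scene.cells["dist_to_rm_m"].to_numpy() > 0, inside)

    def test_depth_positive_and_shoals_toward_shore(self, small_scene):
        cells = small_scene.cells
        assert (cells["depth_min_m"] >= 0).all()
        pts = shapely.points(cells["x"], cells["y"])
        d_shore = shapely.distance(pts, small_scene.shoreline)
        near = cells["depth_min_m"][d_shore < 1.5 * small_scene.config.cell_m]
        far = cells["depth_min_m"][d_shore >= 1.5 * small_scene.config.cell_m]
        assert near.mean() < far.mean()

    def test_every_cell_has_one_river(self, small_scene):
        assert small_scene.cells["river"].isin(["A", "B", "C"]).all()

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            EstuaryConfig(cell_m=0.0)
        with pytest.raises(ValueError):
            EstuaryConfig(nx=2)
        with pytest.raises(ValueError):
            EstuaryConfig(river_cols={})


class TestEnvironment:
    def test_zero_noise_gives_deterministic_mean_surface(self, small_scene):
        cfg = EnvConfig(temp_noise=0.0, do_noise=0.0, salin_noise=0.0,
                        ph_noise=0.0)
        a = EnvFieldSeries(small_scene, cfg, seed=1)
        b = EnvFieldSeries(small_scene, cfg, seed=2)
        d = dt.date(2015, 7, 1)
        fa, fb = a.fields(d), b.fields(d)
        # the only remaining stochastic term is the estuary-wide daily
        # temperature anomaly, shared across cells: remove it and the
        # fields must be identical between seeds
        anomaly = (fa["avg_temp"] - fb["avg_temp"]).round(9).unique()
        assert len(anomaly) == 1
        pd.testing.assert_series_equal(fa["avg_salin"] - fb["avg_salin"],
                                       pd.Series(0.0, index=fa.index),
                                       check_names=False)

    def test_values_within_clipping_envelope(self, small_env):
        for day in (dt.date(2011, 1, 15), dt.date(2014, 7, 4),
                    dt.date(2019, 10, 1)):
            f = small_env.fields(day)
            assert f["avg_temp"].between(14.7, 35.8).all()
            assert f["avg_do"].between(0.4, 11.9).all()
            assert f["avg_salin"].between(0.1, 35.9).all()

    def test_salinity_declines_upriver_every_day(self, small_scene, small_env):
        """River-head salinity is below estuary-mouth salinity daily."""
        cells = small_scene.cells
        head = cells["dist_to_rm_m"].idxmax()
        mouth = (cells["dist_to_rm_m"] - 0).abs().idxmin()
        rng = np.random.default_rng(0)
        days = [dt.date(2012, 1, 1) + dt.timedelta(days=int(d))
                for d in rng.integers(0, 3000, 25)]
        for day in days:
            f = small_env.fields(day)
            assert f.loc[head, "avg_salin"] < f.loc[mouth, "avg_salin"]

    def test_dates_before_epoch_rejected(self, small_env):
        with pytest.raises(ValueError):
            small_env.fields(dt.date(2009, 12, 31))

    def test_fields_deterministic_per_day(self, small_scene):
        a = EnvFieldSeries(small_scene, seed=5)
        b = EnvFieldSeries(small_scene, seed=5)
        d = dt.date(2016, 4, 1)
        pd.testing.assert_frame_equal(a.fields(d), b.fields(d))


class TestSurveySim:
    def test_deterministic(self, small_scene, small_env, truth):
        design = SurveyDesign(years=(2010, 2010))
        a = simulate_survey(small_scene, small_env, truth, design, seed=9)
        b = simulate_survey(small_scene, small_env, truth, design, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_sets_only_in_shallow_cells(self, small_survey):
        assert (small_survey["depth_min_m"] <= 3.0).all()

    def test_offset_linearity(self, small_scene, small_env):
        """With a constant linear predictor, doubling soak time doubles
        the mean catch (within Monte-Carlo error)."""
        flat = TrueModel(intercept=-9.5, effects={}, dispersion=2.0)
        d1 = SurveyDesign(years=(2010, 2012), soak_minutes=30.0)
        d2 = SurveyDesign(years=(2010, 2012), soak_minutes=60.0)
        s1 = simulate_survey(small_scene, small_env, flat, d1, seed=21)
        s2 = simulate_survey(small_scene, small_env, flat, d2, seed=22)
        m1, m2 = s1["n_caught"].mean(), s2["n_caught"].mean()
        ratio = m2 / m1
        se = ratio * np.sqrt(s1["n_caught"].var() / (len(s1) * m1 ** 2)
                             + s2["n_caught"].var() / (len(s2) * m2 ** 2))
        assert abs(ratio - 2.0) < 3 * se

    def test_zero_fraction_matches_formula(self, small_scene, small_env):
        """Observed zero-catch proportion agrees with the average
        closed-form Tweedie zero mass."""
        flat = TrueModel(intercept=-9.0, effects={}, power=1.6,
                         dispersion=30.0)
        s = simulate_survey(small_scene, small_env, flat,
                            SurveyDesign(years=(2010, 2013)), seed=23)
        mu = s["effort_yard_min"].to_numpy() * np.exp(-9.0)
        expect = tweedie_zero_mass(mu, 1.6, 30.0).mean()
        got = (s["n_caught"] == 0).mean()
        se = np.sqrt(expect * (1 - expect) / len(s))
        assert abs(got - expect) < 4 * se

    def test_fish_count_matches_length_lists(self, small_survey):
        n_list = small_survey["lengths_stl_m"].str.split(";").apply(
            lambda v: 0 if v == [""] else len(v))
        np.testing.assert_array_equal(small_survey["n_fish"].to_numpy(),
                                      n_list.to_numpy())

    def test_default_calibration_is_sparse(self):
        """Default world: ~2500 sets over 13 years with total catch on
        the order of one hundred juveniles."""
        scene = generate_scene(seed=0)
        env = EnvFieldSeries(scene, seed=0)
        s = simulate_survey(scene, env, TrueModel(), seed=0)
        assert 2300 <= len(s) <= 2800
        assert 40 <= s["n_caught"].sum() <= 250


class TestSightings:
    def test_uniform_density_chisquare(self, small_scene, small_env):
        flat = TrueModel(intercept=-10.0, effects={})
        sig = simulate_sightings(small_scene, small_env, flat, 5000,
                                 seed=31, density="uniform")
        counts = sig["cell"].value_counts()
        valid = small_scene.cells.index[
            small_scene.cells["depth_min_m"] <= 3.0]
        obs = np.array([counts.get(int(c), 0) for c in valid])
        chi2, p = stats.chisquare(obs)
        assert p > 0.001

    def test_degenerate_density_single_cell(self, small_scene, small_env, truth):
        valid = small_scene.cells.index[
            small_scene.cells["depth_min_m"] <= 3.0].to_numpy()
        w = np.zeros(len(valid))
        w[7] = 1.0
        sig = simulate_sightings(small_scene, small_env, truth, 100,
                                 seed=32, cell_weights=w)
        assert (sig["cell"] == int(valid[7])).all()

    def test_counts_proportional_to_weights(self, small_scene, small_env, truth):
        """Observed sighting counts regress on expected with slope ~1."""
        valid = small_scene.cells.index[
            small_scene.cells["depth_min_m"] <= 3.0].to_numpy()
        rng = np.random.default_rng(33)
        w = rng.gamma(2.0, 1.0, len(valid))
        w /= w.sum()
        n = 10_000
        sig = simulate_sightings(small_scene, small_env, truth, n,
                                 seed=34, cell_weights=w)
        counts = sig["cell"].value_counts()
        obs = np.array([counts.get(int(c), 0) for c in valid])
        expect = n * w
        slope = np.sum(obs * expect) / np.sum(expect ** 2)
        assert slope == pytest.approx(1.0, abs=0.05)

    def test_requires_valid_cells_and_n(self, small_scene, small_env, truth):
        with pytest.raises(ValueError):
            simulate_sightings(small_scene, small_env, truth, 0, seed=1)
        with pytest.raises(ValueError):
            simulate_sightings(small_scene, small_env, truth, 10, seed=1,
                               max_depth_m=-1.0)
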