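"""Prediction grid, posterior abundance totals, trimming, trend tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sawdens import build_prediction_grid, compare_years, interannual_change
from sawdens.abundance import AbundanceDraws, estimate_abundance


class TestPredictionGrid:
    def test_clip_rules(self, small_scene, small_survey):
        grid = build_prediction_grid(small_scene, small_survey)
        assert (grid.cells["depth_min_m"] <= 3.0).all()
        assert (grid.cells["soak_area_yd2"] > 0).all()
        # no retained polygon extends beyond the 61 m shoreline buffer
        buffer = small_scene.shoreline.buffer(61.0)
        for _, row in grid.cells.iterrows():
            poly = small_scene.microgrids[int(row["microgrid_id"])]
            clipped = poly.intersection(buffer)
            assert clipped.area == pytest.approx(row["area_m2"], rel=1e-9)

    def test_depth_boundary_inclusive(self, small_scene, small_survey):
        """Cells at exactly the 3 m limit are retained (> 3 m removed)."""
        scene = small_scene
        cells = scene.cells.copy()
        probe = cells.index[cells["depth_min_m"] <= 3.0][0]
        cells.loc[probe, "depth_min_m"] = 3.0
        import dataclasses

        scene2 = dataclasses.replace(scene, cells=cells)
        grid = build_prediction_grid(scene2, small_survey)
        assert int(cells.loc[probe, "microgrid_id"]) in set(
            grid.cells["microgrid_id"])

    def test_area_against_independent_geometry(self, small_scene, small_survey):
        """Total grid area equals a direct shapely recomputation."""
        grid = build_prediction_grid(small_scene, small_survey)
        buffer = small_scene.shoreline.buffer(61.0)
        keep = small_scene.cells["depth_min_m"] <= 3.0
        expect = sum(
            small_scene.microgrids[int(i)].intersection(buffer).area
            for i in small_scene.cells.loc[keep, "microgrid_id"])
        assert grid.cells["area_m2"].sum() == pytest.approx(expect, rel=1e-9)

    def test_sampled_subset_of_full(self, small_scene, small_survey):
        grid = build_prediction_grid(small_scene, small_survey)
        assert grid.cells["in_sampling_universe"].sum() <= grid.n_cells


class _ConstantResult:
    def __init__(self, etas):
        self.etas = np.atleast_1d(etas)  # one value per "draw"

    def linear_predictor(self, frame, params=None):
        if params is None:
            return np.full(len(frame), self.etas[0])
        return np.tile(self.etas, (len(frame), 1))


class TestEstimation:
    def test_constant_density_closed_form(self, small_scene, small_env,
                                          small_survey):
        """Density d over area A gives abundance d * A exactly, with zero
        spread when all draws coincide."""
        grid = build_prediction_grid(small_scene, small_survey)
        eta = -8.0
        res = _ConstantResult([eta] * 5)
        ab = estimate_abundance(res, np.zeros((5, 1)), grid, small_env,
                                [2012], seasons=("Spring/Summer",))
        area = grid.cells["soak_area_yd2"].sum()
        expect = area * np.exp(eta)
        full = ab.totals[:, 0, 0, 1]
        np.testing.assert_allclose(full, expect, rtol=1e-12)
        assert ab.summary().query("domain=='full'")["sd"].iloc[0] == 0.0

    def test_sampled_never_exceeds_full(self, small_scene, small_env,
                                        small_survey, fitted):
        grid = build_prediction_grid(small_scene, small_survey)
        draws = fitted.sample_posterior(40, seed=2, sampler="gaussian")
        ab = estimate_abundance(fitted, draws, grid, small_env,
                                [2011, 2012])
        assert np.all(ab.totals[..., 0] <= ab.totals[..., 1] + 1e-9)

    def test_infinite_trim_factor_is_noop(self):
        rng = np.random.default_rng(3)
        totals = rng.lognormal(0, 3, size=(200, 1, 1, 1))
        tr = AbundanceDraws(totals, [2010], ("Spring/Summer",), ("full",),
                            trim_factor=np.inf)
        assert tr.retained.all()

    def test_trimming_removes_extreme_draws(self):
        totals = np.ones((100, 1, 1, 1))
        totals[0] = 1e6  # five orders of magnitude above the median
        tr = AbundanceDraws(totals, [2010], ("Spring/Summer",), ("full",),
                            trim_factor=100.0)
        assert not tr.retained[0, 0, 0, 0]
        assert tr.retained[1:].all()
        assert tr.summary()["n_draws"].iloc[0] == 99


class TestTrend:
    def _draws(self, means, sd=1.0, n=200, seed=0):
        rng = np.random.default_rng(seed)
        totals = np.stack([rng.normal(m, sd, n) for m in means], axis=1)
        totals = np.abs(totals)[:, :, None, None]
        return AbundanceDraws(totals, list(range(2010, 2010 + len(means))),
                              ("Spring/Summer",), ("sampled",))

    def test_identical_years_share_a_letter(self):
        ab = self._draws([50.0, 50.0, 50.0], sd=5.0, seed=1)
        out = compare_years(ab, domain="sampled")
        assert len(set(out["letters"])) == 1

    def test_separated_years_get_distinct_letters(self):
        ab = self._draws([50.0, 150.0], sd=5.0, seed=2)
        out = compare_years(ab, domain="sampled")
        assert set(out["letters"]) == {"a", "b"}

    def test_letters_match_textbook_tukey(self):
        """Compact letters agree with a from-scratch studentized-range
        Tukey computation on three groups."""
        ab = self._draws([40.0, 44.0, 90.0], sd=6.0, n=30, seed=3)
        out = compare_years(ab, domain="sampled")
        groups = [ab.totals[:, i, 0, 0] for i in range(3)]
        n = len(groups[0])
        k = len(groups)
        mse = np.mean([g.var(ddof=1) for g in groups])
        dof = k * (n - 1)
        qcrit = stats.studentized_range.ppf(0.95, k, dof)
        sig = {}
        for i in range(k):
            for j in range(i + 1, k):
                q = abs(groups[i].mean() - groups[j].mean()) / np.sqrt(mse / n)
                sig[(i, j)] = q > qcrit
        letters = out["letters"].to_list()
        for (i, j), different in sig.items():
            share = bool(set(letters[i]) & set(letters[j]))
            assert share != different

    def test_single_year_identity_letter(self):
        ab = self._draws([50.0], sd=5.0)
        out = compare_years(ab, domain="sampled")
        assert out["letters"].to_list() == ["a"]


class TestInterannualChange:
    def test_constant_series_all_ratios_one(self):
        out = interannual_change([40.0, 40.0, 40.0])
        np.testing.assert_allclose(out["ratios"], 1.0)

    def test_printed_style_arithmetic(self):
        out = interannual_change([100.0, 50.0, 50.0])
        np.testing.assert_allclose(out["ratios"], [0.5, 1.0])
        assert out["mean"] == pytest.approx(0.75)

    def test_random_series_against_recomputation(self):
        rng = np.random.default_rng(4)
        v = rng.uniform(10, 100, 12)
        out = interannual_change(v)
        np.testing.assert_allclose(out["ratios"], v[1:] / v[:-1], rtol=1e-15)
        assert out["mean"] == pytest.approx(np.mean(v[1:] / v[:-1]))

    def test_errors(self):
        with pytest.raises(ValueError):
            interannual_change([5.0])
        with pytest.raises(ValueError):
            interannual_change([5.0, 0.0])
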