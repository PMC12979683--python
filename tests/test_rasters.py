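"""Raster toolchain: signatures, maximum-likelihood classification,
shoreline distance, focal sums, zonal statistics — each against an
independent brute-force or hand-computed oracle."""

import numpy as np
import pytest
import shapely
from shapely.geometry import LineString, box

from sawdens.experiments import focal_sum_bruteforce, mlc_bruteforce
from sawdens.rasters import (
    ClassSignature,
    Raster,
    classify_mlc,
    mangrove_distance_to_shore,
    mangrove_focal_sum,
    train_signatures,
    uniform_priors,
    urban_priors,
    zonal_stats,
)


class TestFocalSum:
    def test_full_raster_interior_is_64(self):
        r = mangrove_focal_sum(Raster(np.ones((16, 16), dtype=np.uint8)))
        # interior cells with a complete -4..+3 window
        assert np.all(r.data[4:13, 4:13] == 64)

    def test_isolated_cell_is_one(self):
        m = np.zeros((16, 16), dtype=np.uint8)
        m[8, 8] = 1
        r = mangrove_focal_sum(Raster(m))
        assert r.data[8, 8] == 1
        assert np.isnan(r.data[0, 0])

    def test_matches_bruteforce_on_random_mask(self):
        rng = np.random.default_rng(9)
        m = (rng.random((16, 16)) < 0.4).astype(np.uint8)
        fast = mangrove_focal_sum(Raster(m)).data
        slow = focal_sum_bruteforce(m.astype(bool))
        np.testing.assert_array_equal(np.isnan(fast), np.isnan(slow))
        np.testing.assert_array_equal(fast[~np.isnan(fast)],
                                      slow[~np.isnan(slow)])

    def test_values_in_range_and_translation_invariant(self):
        rng = np.random.default_rng(10)
        m = (rng.random((20, 20)) < 0.5).astype(np.uint8)
        vals = mangrove_focal_sum(Raster(m)).data
        on = vals[~np.isnan(vals)]
        assert on.min() >= 1 and on.max() <= 64
        # translate the mask away from edges: interior sums must shift with it
        big = np.zeros((40, 40), dtype=np.uint8)
        big[10:30, 10:30] = m
        shifted = mangrove_focal_sum(Raster(big)).data[14:26, 14:26]
        np.testing.assert_array_equal(vals[4:16, 4:16], shifted)


class TestSignatures:
    def _image(self, rng, means, n=24):
        data = np.stack([rng.normal(m, 1.0, (n, n)) for m in means])
        return Raster(data, x0=0.0, y0=float(n), cell=1.0)

    def test_identical_pixels_ridge_applied(self):
        img = Raster(np.full((3, 8, 8), 5.0), x0=0, y0=8, cell=1)
        pts = np.array([[1.5, 1.5], [2.5, 2.5], [3.5, 3.5], [4.5, 4.5]])
        with pytest.warns(UserWarning, match="singular"):
            sigs = train_signatures(img, pts, ["mangrove"] * 4)
        assert np.allclose(sigs[0].mean, 5.0)
        assert np.all(np.linalg.eigvalsh(sigs[0].cov) > 0)

    def test_recovers_known_gaussian_means(self):
        """30 points per class from known band Gaussians recover the class
        means within 3 standard errors."""
        rng = np.random.default_rng(3)
        img = self._image(rng, [4.0, 7.0, 2.0])
        pts = rng.uniform(1, 23, (90, 2))
        labels = np.repeat(["mangrove", "other_vegetation", "non_vegetation"], 30)
        sigs = train_signatures(img, pts, labels)
        for sig in sigs:
            se = np.sqrt(np.diag(sig.cov) / sig.n)
            assert np.all(np.abs(sig.mean - [4.0, 7.0, 2.0]) < 3 * se + 0.5)

    def test_point_outside_extent_rejected(self):
        img = self._image(np.random.default_rng(0), [1, 2, 3], n=8)
        with pytest.raises(ValueError):
            train_signatures(img, np.array([[99.0, 1.0]] * 4), ["m"] * 4)


class TestMLC:
    def _setup(self, seed=4, n=16):
        rng = np.random.default_rng(seed)
        image = np.stack([rng.normal(m, 1.0, (n, n)) for m in (2.0, 5.0, 8.0)])
        sigs = [
            ClassSignature("mangrove", [2.2, 4.8, 8.1], np.eye(3), 30),
            ClassSignature("other_vegetation", [1.5, 5.5, 7.5], np.eye(3), 30),
            ClassSignature("non_vegetation", [2.5, 4.5, 8.5], np.eye(3), 30),
        ]
        return rng, Raster(image), sigs

    def test_equal_spherical_covariances_reduce_to_nearest_mean(self):
        _, img, sigs = self._setup()
        classes, _ = classify_mlc(img, sigs, uniform_priors(img.shape))
        x = img.data.reshape(3, -1).T
        means = np.array([s.mean for s in sigs])
        nearest = np.argmin(((x[:, None, :] - means) ** 2).sum(-1), axis=1)
        np.testing.assert_array_equal(classes.ravel(), nearest)

    def test_urban_prior_beats_equal_likelihoods(self):
        """With equal likelihoods an urban pixel goes non-mangrove since
        0.02 < 0.49."""
        sigs = [ClassSignature(lbl, [1.0], [[1.0]], 10)
                for lbl in ("mangrove", "other_vegetation", "non_vegetation")]
        img = Raster(np.full((1, 2, 2), 1.0))
        priors = urban_priors(np.ones((2, 2), dtype=bool))
        classes, mang = classify_mlc(img, sigs, priors)
        assert not mang.any()

    def test_two_run_protocol_equals_composite_priors(self):
        """Classifying urban and non-urban pixels in two separate runs
        gives exactly the composite single-run result."""
        rng, img, sigs = self._setup(seed=5)
        urban = rng.random(img.shape) < 0.4
        composite, _ = classify_mlc(img, sigs, urban_priors(urban))
        run_urban, _ = classify_mlc(img, sigs, urban_priors(np.ones_like(urban)))
        run_rural, _ = classify_mlc(img, sigs, uniform_priors(img.shape))
        merged = np.where(urban, run_urban, run_rural)
        np.testing.assert_array_equal(composite, merged)

    def test_matches_bruteforce(self):
        rng, img, sigs = self._setup(seed=6)
        priors = urban_priors(rng.random(img.shape) < 0.3)
        fast, _ = classify_mlc(img, sigs, priors)
        slow = mlc_bruteforce(img.data, sigs, priors)
        np.testing.assert_array_equal(fast, slow)

    def test_prior_scaling_invariance(self):
        _, img, sigs = self._setup(seed=7)
        a, _ = classify_mlc(img, sigs, uniform_priors(img.shape))
        b, _ = classify_mlc(img, sigs, 3.0 * uniform_priors(img.shape))
        np.testing.assert_array_equal(a, b)

    def test_all_zero_priors_rejected(self):
        _, img, sigs = self._setup(seed=8)
        priors = np.zeros((3, *img.shape))
        with pytest.raises(ValueError):
            classify_mlc(img, sigs, priors)


class TestShoreDistance:
    def test_cell_on_shoreline_distance_zero(self):
        m = np.zeros((5, 5), dtype=np.uint8)
        m[2, 2] = 1
        shoreline = LineString([(0, 2.5), (5, 2.5)])  # through the centre row
        r = mangrove_distance_to_shore(Raster(m, x0=0, y0=5, cell=1), shoreline)
        assert r.data[2, 2] == pytest.approx(0.0, abs=1e-9)

    def test_beyond_buffer_is_null(self):
        m = np.zeros((1, 2), dtype=np.uint8)
        m[0, :] = 1
        shoreline = LineString([(0.5, 0.5), (0.5, 10.0)])
        # cell centres at x = 0.5 (on the line) and x = 10.6+0.5... use wide cells
        r = mangrove_distance_to_shore(
            Raster(m, x0=0, y0=1, cell=1.0), shoreline, buffer_m=10.0)
        assert r.data[0, 0] == pytest.approx(0.0, abs=1e-9)
        m2 = np.ones((1, 1), dtype=np.uint8)
        r2 = mangrove_distance_to_shore(
            Raster(m2, x0=10.6, y0=1, cell=1.0), shoreline, buffer_m=10.0)
        assert np.isnan(r2.data[0, 0])  # centre 10.6 m away

    def test_against_densified_bruteforce(self):
        rng = np.random.default_rng(11)
        m = (rng.random((12, 12)) < 0.5).astype(np.uint8)
        shoreline = LineString([(0, 0), (12, 4), (6, 12)])
        r = mangrove_distance_to_shore(
            Raster(m, x0=0, y0=12, cell=1.0), shoreline, buffer_m=50.0)
        # brute force against densely interpolated shoreline points
        s = np.linspace(0, shoreline.length, 20000)
        pts = np.array([shoreline.interpolate(t).coords[0] for t in s])
        xs, ys = Raster(m, x0=0, y0=12, cell=1.0).cell_centers()
        for i, j in zip(*np.nonzero(m)):
            d_brute = np.min(np.hypot(pts[:, 0] - xs[i, j], pts[:, 1] - ys[i, j]))
            assert abs(r.data[i, j] - d_brute) < 0.5 * 1.0

    def test_empty_shoreline_rejected(self):
        with pytest.raises(ValueError):
            mangrove_distance_to_shore(
                Raster(np.ones((2, 2), dtype=np.uint8)), LineString())


class TestZonal:
    def test_singleton_grid(self):
        """A grid with one mangrove cell 3 m from shore and focal sum 5."""
        dist = np.full((4, 4), np.nan)
        focal = np.full((4, 4), np.nan)
        dist[1, 1], focal[1, 1] = 3.0, 5.0
        grids = [box(0, 0, 4, 4)]
        out = zonal_stats(grids, Raster(dist, x0=0, y0=4, cell=1),
                          Raster(focal, x0=0, y0=4, cell=1))
        assert out.loc[0, "min_mdts"] == 3.0
        assert out.loc[0, "sum_mnn"] == 5.0

    def test_mangrove_free_grid_is_zero_sum(self):
        empty = np.full((4, 4), np.nan)
        out = zonal_stats([box(0, 0, 4, 4)],
                          Raster(empty, x0=0, y0=4, cell=1),
                          Raster(empty, x0=0, y0=4, cell=1))
        assert out.loc[0, "sum_mnn"] == 0.0
        assert np.isnan(out.loc[0, "min_mdts"])

    def test_mass_conservation_over_tiling(self):
        """Sum of per-grid focal totals equals the whole-raster total."""
        rng = np.random.default_rng(12)
        m = (rng.random((16, 16)) < 0.4).astype(np.uint8)
        focal = mangrove_focal_sum(Raster(m, x0=0, y0=16, cell=1))
        dist = Raster(np.where(m, 1.0, np.nan), x0=0, y0=16, cell=1)
        grids = [box(x, y, x + 4, y + 4)
                 for x in range(0, 16, 4) for y in range(0, 16, 4)]
        out = zonal_stats(grids, dist, focal)
        assert out["sum_mnn"].sum() == pytest.approx(np.nansum(focal.data))
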