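"""Region models, energy bookkeeping, and level-set evolution."""

import numpy as np
import pytest
from scipy import ndimage

import strokeseg as ss
from strokeseg.levelset import (
    HIST_EPS,
    SD_FLOOR,
    GaussianModel,
    HistogramModel,
    LevelSetState,
    StageParams,
    energy,
    evolve,
    fit_gaussian_model,
    fit_histogram_model,
    gradient_map,
    log_prob_map,
    signed_distance,
)


def _vol(values):
    return ss.ScalarVolume(np.asarray(values, dtype=float))


def _region_vol(values):
    """A 3D volume whose first voxels hold `values`, plus a matching mask."""
    values = np.asarray(values, dtype=float)
    grid = np.zeros((max(2, values.size), 2, 1))
    grid[: values.size, 0, 0] = values
    mask = np.zeros(grid.shape, dtype=bool)
    mask[: values.size, 0, 0] = True
    return _vol(grid), mask


class TestGaussianModel:
    def test_degenerate_region_clamps_sd(self):
        img, mask = _region_vol([0.4, 0.4, 0.4])
        m = fit_gaussian_model(img, mask)
        assert m.mean == pytest.approx(0.4)
        assert m.sd == SD_FLOOR

    def test_ml_estimator(self):
        # divide-by-n sd of {0.2, 0.4, 0.6} is sqrt(0.08/3) ~ 0.16330
        img, mask = _region_vol([0.2, 0.4, 0.6])
        m = fit_gaussian_model(img, mask)
        assert m.mean == pytest.approx(0.4)
        assert m.sd == pytest.approx(np.sqrt(0.08 / 3), abs=1e-12)
        assert m.sd == pytest.approx(0.1633, abs=5e-5)

    def test_log_density_symmetric_about_mean(self):
        m = GaussianModel(0.4, 0.1)
        for delta in (0.01, 0.05, 0.3):
            assert m.log_prob(0.4 + delta) == pytest.approx(m.log_prob(0.4 - delta))

    def test_density_maximum_at_mean(self):
        m = GaussianModel(0.5, 0.2)
        assert m.log_prob(0.5) == pytest.approx(np.log(1 / (0.2 * np.sqrt(2 * np.pi))))

    def test_empty_region_rejected(self):
        img, mask = _region_vol([0.1, 0.2])
        with pytest.raises(ValueError, match="empty-region"):
            fit_gaussian_model(img, np.zeros_like(mask))


class TestHistogramModel:
    def test_single_occupied_bin_gets_all_mass(self):
        img, mask = _region_vol([0.505, 0.507, 0.509])
        m = fit_histogram_model(img, mask, n_bins=64)
        assert m.mass.max() == pytest.approx(1.0, abs=1e-6)

    def test_uniform_coverage_gives_equal_mass(self):
        n_bins = 8
        centers = (np.arange(n_bins) + 0.5) / n_bins
        img, mask = _region_vol(centers)
        m = fit_histogram_model(img, mask, n_bins=n_bins)
        assert np.allclose(m.mass, 1.0 / n_bins)

    def test_empty_bin_floored_to_finite_log(self):
        img, mask = _region_vol([0.1, 0.1, 0.1])
        m = fit_histogram_model(img, mask, n_bins=4)
        lp = m.log_prob(0.9)  # empty bin
        assert np.isfinite(lp)
        assert lp == pytest.approx(np.log(HIST_EPS), abs=0.01)

    def test_mass_sums_to_one(self):
        rng = np.random.default_rng(0)
        img = _vol(rng.random((6, 6, 2)))
        m = fit_histogram_model(img, np.ones(img.shape, bool))
        assert m.mass.sum() == pytest.approx(1.0, abs=1e-9)

    def test_empty_region_rejected(self):
        img, mask = _region_vol([0.1, 0.2])
        with pytest.raises(ValueError, match="empty-region"):
            fit_histogram_model(img, np.zeros_like(mask))


class TestLogProbMap:
    @pytest.mark.parametrize("kind", ["gaussian", "histogram"])
    def test_matches_per_voxel_brute_force(self, kind):
        rng = np.random.default_rng(7)
        img = _vol(rng.random((5, 5, 2)))
        region = rng.random((5, 5, 2)) > 0.4
        if kind == "gaussian":
            m = fit_gaussian_model(img, region)
            expected = np.array(
                [[[float(m.log_prob(v)) for v in col] for col in row] for row in img.values]
            )
        else:
            m = fit_histogram_model(img, region, n_bins=8)
            expected = np.empty(img.shape)
            for idx in np.ndindex(img.shape):
                v = img.values[idx]
                b = min(int(v * 8), 7)  # brute-force bin lookup over [0,1]
                expected[idx] = np.log(m.mass[b])
        got = log_prob_map(m, img).values
        assert np.allclose(got, expected, atol=1e-12)
        assert np.all(np.isfinite(got))


class TestGradientMap:
    def test_extremes_map_to_one_and_zero(self):
        rng = np.random.default_rng(1)
        vals = 0.5 + 0.05 * rng.standard_normal((8, 8, 2))
        vals[0, 0, 0] = 0.5  # near the CV mean -> minimal energy
        vals[1, 0, 0] = 0.95  # far outlier -> maximal energy
        img = _vol(vals)
        cv = np.zeros(img.shape, bool)
        cv[2:6, 2:6, :] = True
        g = gradient_map(img, cv).values
        assert g.min() >= 0.0 and g.max() <= 1.0
        # the voxel attaining the minimum energy (intensity nearest the CV
        # mean) gets g = 1; the maximum-energy voxel gets g = 0
        cv_mean = img.values[cv].mean()
        nearest = np.unravel_index(np.argmin(np.abs(vals - cv_mean)), g.shape)
        farthest = np.unravel_index(np.argmax(np.abs(vals - cv_mean)), g.shape)
        assert g[nearest] == pytest.approx(1.0, abs=1e-6)
        assert g[farthest] == pytest.approx(0.0, abs=1e-12)

    def test_matches_hand_composed_formula(self):
        rng = np.random.default_rng(3)
        img = _vol(rng.random((4, 4, 1)))
        cv = np.zeros((4, 4, 1), bool)
        cv[1:3, 1:3, 0] = True
        mu = img.values[cv].mean()
        sd = max(img.values[cv].std(), SD_FLOOR)
        e = 0.5 * ((img.values - mu) / sd) ** 2 + np.log(sd * np.sqrt(2 * np.pi))
        e = (e - e.min()) / (e.max() - e.min())
        assert np.allclose(gradient_map(img, cv).values, 1.0 - e**2, atol=1e-12)

    def test_constant_image_gives_all_ones(self):
        img = _vol(np.full((4, 4, 2), 0.5))
        cv = np.ones((4, 4, 2), bool)
        assert np.all(gradient_map(img, cv).values == 1.0)


def _brute_force_energy(phi, domain, img, obj, bg, params, g=None):
    """Independent term-by-term summation over voxels and faces."""
    obj_mask = (phi >= 0) & domain
    bg_mask = domain & ~obj_mask
    total = params.mu * obj_mask.sum()
    for idx in np.ndindex(img.shape):
        if obj_mask[idx]:
            total -= float(obj.log_prob(img.values[idx]))
        elif bg_mask[idx]:
            total -= float(bg.log_prob(img.values[idx]))
    # perimeter: every neighboring in-domain pair with differing labels
    shape = img.shape
    for idx in np.ndindex(shape):
        for axis in range(3):
            nb = list(idx)
            nb[axis] += 1
            nb = tuple(nb)
            if nb[axis] >= shape[axis]:
                continue
            if domain[idx] and domain[nb] and obj_mask[idx] != obj_mask[nb]:
                w = 1.0 if g is None else 0.5 * (g[idx] + g[nb])
                total += params.alpha * w
    return total


class TestEnergy:
    def test_empty_object_is_background_sum(self):
        rng = np.random.default_rng(5)
        img = _vol(rng.random((4, 4, 2)))
        obj = GaussianModel(0.7, 0.1)
        bg = GaussianModel(0.3, 0.1)
        params = StageParams(alpha=0, mu=0)
        state = LevelSetState(phi=-np.ones(img.shape), domain_mask=np.ones(img.shape, bool))
        expected = -bg.log_prob(img.values).sum()
        assert energy(state, img, obj, bg, params) == pytest.approx(expected, abs=1e-9)

    def test_area_term_is_mu_times_object_count(self):
        rng = np.random.default_rng(6)
        img = _vol(rng.random((5, 5, 2)))
        phi = rng.standard_normal(img.shape)
        obj = GaussianModel(0.7, 0.1)
        bg = GaussianModel(0.3, 0.1)
        state = LevelSetState(phi=phi, domain_mask=np.ones(img.shape, bool))
        e0 = energy(state, img, obj, bg, StageParams(alpha=0, mu=0))
        e1 = energy(state, img, obj, bg, StageParams(alpha=0, mu=1.5))
        n_obj = (phi >= 0).sum()
        assert e1 - e0 == pytest.approx(1.5 * n_obj, abs=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_summation(self, seed):
        rng = np.random.default_rng(seed)
        img = _vol(rng.random((6, 6, 1)))
        phi = rng.standard_normal(img.shape)
        domain = rng.random(img.shape) > 0.2
        g = _vol(rng.random(img.shape))
        obj = GaussianModel(0.6, 0.15)
        bg = GaussianModel(0.35, 0.2)
        params = StageParams(alpha=1.7, mu=0.8)
        state = LevelSetState(phi=phi, domain_mask=domain)
        expected = _brute_force_energy(phi, domain, img, obj, bg, params, g.values)
        assert energy(state, img, obj, bg, params, g=g) == pytest.approx(expected, abs=1e-9)

    def test_checkerboard_object_matches_brute_force(self):
        rng = np.random.default_rng(11)
        img = _vol(rng.random((6, 6, 1)))
        xx, yy = np.meshgrid(np.arange(6), np.arange(6), indexing="ij")
        phi = np.where(((xx + yy) % 2 == 0), 1.0, -1.0)[:, :, None]
        domain = np.ones(img.shape, bool)
        obj = GaussianModel(0.7, 0.1)
        bg = GaussianModel(0.3, 0.1)
        params = StageParams(alpha=2.0, mu=1.0)
        state = LevelSetState(phi=phi, domain_mask=domain)
        expected = _brute_force_energy(phi, domain, img, obj, bg, params)
        assert energy(state, img, obj, bg, params) == pytest.approx(expected, abs=1e-9)

    def test_shape_mismatch_rejected(self):
        img = _vol(np.zeros((4, 4, 2)))
        state = LevelSetState(phi=np.ones((5, 5, 2)), domain_mask=np.ones((5, 5, 2), bool))
        with pytest.raises(ValueError):
            energy(state, img, GaussianModel(0, 1), GaussianModel(0, 1), StageParams())


class TestEvolve:
    def _models(self):
        return GaussianModel(0.7, 0.03, fixed=True), GaussianModel(0.3, 0.03, fixed=True)

    def test_converges_to_ml_classification(self, two_population_volume):
        img, truth = two_population_volume
        obj, bg = self._models()
        params = StageParams(
            alpha=0, mu=0, n_iter=400, object_fixed=True, background_fixed=True
        )
        x, y, z = np.ogrid[:64, :64, :8]
        init = ((x - 40) / 10.0) ** 2 + ((y - 24) / 10.0) ** 2 + ((z - 4) / 2.0) ** 2 <= 1
        mask = evolve(img, init, obj, bg, params)
        ml = obj.log_prob(img.values) > bg.log_prob(img.values)
        band = ndimage.binary_dilation(truth) & ~ndimage.binary_erosion(truth)
        assert np.array_equal(mask[~band], ml[~band])

    def test_exact_truth_init_is_stationary(self):
        x, y, z = np.ogrid[:16, :16, :4]
        truth = ((x - 8) ** 2 + (y - 8) ** 2 <= 16) & (z < 4)
        img = _vol(np.where(truth, 0.7, 0.3))
        obj, bg = self._models()
        params = StageParams(alpha=0, mu=0, n_iter=50, object_fixed=True, background_fixed=True)
        mask = evolve(img, truth, obj, bg, params)
        assert np.array_equal(mask, truth)

    def test_domain_restriction_freezes_outside(self):
        rng = np.random.default_rng(2)
        img = _vol(rng.random((12, 12, 3)))
        domain = np.zeros(img.shape, bool)
        domain[2:10, 2:10, :] = True
        init = np.zeros(img.shape, bool)
        init[4:8, 4:8, 1] = True
        obj, bg = self._models()
        params = StageParams(alpha=0, mu=0, n_iter=30, object_fixed=True, background_fixed=True)
        mask = evolve(img, init, obj, bg, params, domain=domain)
        assert not np.any(mask & ~domain)

    def test_empty_initialization_rejected(self):
        img = _vol(np.random.default_rng(0).random((8, 8, 2)))
        obj, bg = self._models()
        with pytest.raises(ValueError, match="empty-initialization"):
            evolve(img, np.zeros(img.shape, bool), obj, bg, StageParams(n_iter=5))

    def test_deterministic(self, two_population_volume):
        img, _ = two_population_volume
        obj, bg = self._models()
        params = StageParams(alpha=0.5, mu=0.2, n_iter=40)
        init = np.zeros(img.shape, bool)
        init[20:44, 20:40, 2:6] = True
        m1 = evolve(img, init, obj, bg, params)
        m2 = evolve(img, init, obj, bg, params)
        assert np.array_equal(m1, m2)

    def test_swapping_models_complements_segmentation(self, two_population_volume):
        img, _ = two_population_volume
        obj, bg = self._models()
        params = StageParams(alpha=0, mu=0, n_iter=200, object_fixed=True, background_fixed=True)
        init = np.zeros(img.shape, bool)
        init[16:48, 16:44, 1:7] = True
        m1 = evolve(img, init, obj, bg, params)
        m2 = evolve(img, ~m1, bg, obj, params)
        # up to the never-flipping knife-edge set, the complementary run
        # recovers the complement
        agree = m2 == ~m1
        assert agree.mean() > 0.999

    def test_one_bin_histograms_freeze_the_mask(self):
        rng = np.random.default_rng(9)
        img = _vol(rng.random((10, 10, 2)))
        edges = np.array([0.0, 1.0, 2.0])
        mass = np.array([0.5, 0.5])
        obj = HistogramModel(edges, mass, fixed=True)
        bg = HistogramModel(edges, mass, fixed=True)
        init = rng.random(img.shape) > 0.5
        init[0, 0, 0] = True
        params = StageParams(alpha=0, mu=0, n_iter=30, object_fixed=True, background_fixed=True)
        mask = evolve(img, init, obj, bg, params)
        assert np.array_equal(mask, init)

    @pytest.mark.parametrize("seed", range(10))
    def test_energy_nonincreasing_with_fixed_models(self, seed):
        """With alpha=mu=0 and fixed models every sign flip lowers the energy."""
        rng = np.random.default_rng(seed)
        img = _vol(rng.random((6, 6, 2)))
        obj = GaussianModel(0.7, 0.1, fixed=True)
        bg = GaussianModel(0.3, 0.1, fixed=True)
        params = StageParams(alpha=0, mu=0, object_fixed=True, background_fixed=True)
        domain = np.ones(img.shape, bool)
        init = rng.random(img.shape) > 0.5
        init[0, 0, 0] = True
        phi = np.clip(signed_distance(init), -3, 3)
        force = obj.log_prob(img.values) - bg.log_prob(img.values)
        dt = 0.45 / np.abs(force).max()
        prev = None
        for _ in range(40):
            state = LevelSetState(phi=phi, domain_mask=domain)
            e = energy(state, img, obj, bg, params)
            if prev is not None:
                assert e <= prev + 1e-9
            prev = e
            phi = phi + dt * force
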