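"""Generator contracts: determinism, conservation, planted structure."""

import numpy as np
import pytest

from urbwell.natural_city import GradientZones
from urbwell.street_ecology import CLASSES
from urbwell.synthetic import (
    ConfigurationError,
    SimulationConfig,
    beta_schedule,
    gen_city_panel,
    gen_ntl_series,
    gen_posts,
    gen_streetview_counts,
)


class TestConfig:
    def test_invalid_parameters_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(n_years=1)
        with pytest.raises(ConfigurationError):
            SimulationConfig(grid_shape=(0, 10))
        with pytest.raises(ConfigurationError):
            SimulationConfig(noise_sd=-0.1)
        with pytest.raises(ConfigurationError):
            SimulationConfig(planted_beta={"NOPE": 1.0})

    def test_beta_schedule_validation(self):
        with pytest.raises(ConfigurationError):
            beta_schedule(5, mean0=0.9, mean_step=0.05)  # mean exits (0,1)


class TestNTL:
    def test_same_seed_bit_identical(self, small_cfg):
        a = gen_ntl_series(small_cfg)
        b = gen_ntl_series(small_cfg)
        for ra, rb in zip(a, b):
            np.testing.assert_array_equal(ra.values, rb.values)

    def test_zero_growth_constant_core_footprint(self):
        cfg = SimulationConfig(grid_shape=(60, 60), n_years=4,
                               core_growth=0.0, seed=1)
        series = gen_ntl_series(cfg)
        bright = [r.values > 0.5 * cfg.core_intensity for r in series]
        for b in bright[1:]:
            np.testing.assert_array_equal(b, bright[0])

    def test_core_footprint_monotone_nonshrinking(self, small_cfg):
        series = gen_ntl_series(small_cfg)
        prev = None
        for r in series:
            core = r.values > 0.5 * small_cfg.core_intensity
            if prev is not None:
                assert not np.any(prev & ~core)
            prev = core

    @pytest.mark.parametrize("seed", range(20))
    def test_background_heavy_tailed(self, seed):
        cfg = SimulationConfig(grid_shape=(200, 200), n_years=2,
                               ntl_tail_exponent=1.5, n_cities=1, seed=seed)
        raster = gen_ntl_series(cfg)[0]
        bg = raster.values[raster.values < 0.3 * cfg.core_intensity]
        assert bg.mean() / np.median(bg) > 1.0

    def test_nonnegative_values(self, small_cfg):
        for r in gen_ntl_series(small_cfg):
            assert np.all(r.values >= 0)


class TestPosts:
    def test_exact_count_per_zone(self, disk_zones, small_cfg):
        posts = gen_posts(disk_zones, small_cfg)
        counts = posts.groupby("ring").size()
        assert (counts == small_cfg.posts_per_zone).all()
        assert set(counts.index) == {1, 2, 3}

    def test_posts_fall_inside_their_ring(self, disk_zones, small_cfg):
        from urbwell.raster import RasterGrid
        ref = RasterGrid(np.zeros(disk_zones.label.shape))
        posts = gen_posts(disk_zones, small_cfg, raster=ref)
        for _, p in posts.iterrows():
            r, c = ref.point_to_cell(p["x"], p["y"])
            assert disk_zones.label[r, c] == p["ring"]

    def test_scores_bounded(self, disk_zones, small_cfg):
        posts = gen_posts(disk_zones, small_cfg)
        assert posts["swb"].between(0, 1).all()

    def test_constant_beta_pooled_mean(self, disk_zones):
        cfg = SimulationConfig(
            grid_shape=(40, 40), n_years=3, posts_per_zone=3334, seed=5,
            sentiment_params=[(50.0, 50.0)] * 3)
        posts = gen_posts(disk_zones, cfg)
        assert len(posts) >= 10_000
        assert 0.48 < posts["swb"].mean() < 0.52

    def test_zero_area_zone_skipped_with_warning(self, small_cfg):
        label = np.zeros((10, 10), dtype=np.int32)
        label[:5] = 1
        label[5:] = 3  # ring 2 empty
        zones = GradientZones(label=label, n_rings=3)
        cfg = SimulationConfig(
            grid_shape=(10, 10), n_years=3, posts_per_zone=20, seed=2,
            sentiment_params=[(5, 5)] * 3)
        with pytest.warns(UserWarning, match="U2"):
            posts = gen_posts(zones, cfg)
        assert set(posts["ring"]) == {1, 3}

    def test_planted_rising_mean_recovered_by_ols(self, disk_zones):
        # +0.01 Beta mean per ring; OLS of zone means on ring index
        slopes = []
        for seed in range(10):
            cfg = SimulationConfig(
                grid_shape=(40, 40), n_years=3, posts_per_zone=400,
                seed=seed,
                sentiment_params=beta_schedule(3, mean0=0.6,
                                               mean_step=0.01, conc0=40))
            posts = gen_posts(disk_zones, cfg)
            means = posts.groupby("ring")["swb"].mean()
            slopes.append(np.polyfit(means.index, means.to_numpy(), 1)[0])
        assert np.mean(slopes) > 0
        assert np.mean(slopes) == pytest.approx(0.01, abs=0.005)


class TestStreetviewCounts:
    def test_rows_sum_to_pixel_budget(self, small_cfg):
        mix = np.full(len(CLASSES), 1 / len(CLASSES))
        table = gen_streetview_counts(10, mix, small_cfg)
        assert len(table) == 40  # 4 views per point
        assert (table[list(CLASSES)].sum(axis=1)
                == small_cfg.pixels_per_image).all()

    def test_point_mass_on_vegetation(self, small_cfg):
        table = gen_streetview_counts(5, {"vegetation": 1.0}, small_cfg)
        other = [c for c in CLASSES if c != "vegetation"]
        assert (table[other].to_numpy() == 0).all()
        assert (table["vegetation"] == small_cfg.pixels_per_image).all()

    def test_equal_weights_give_equal_descriptors(self, small_cfg):
        from urbwell.street_ecology import indices_from_table
        mix = {"vegetation": 0.25, "sky": 0.25, "building": 0.25,
               "car": 0.25}
        table = gen_streetview_counts(500, mix, small_cfg)
        idx = indices_from_table(table)
        means = idx[["GN", "GY", "OP", "CR"]].mean()
        # each descriptor expects 4 * 0.25 = 1 under the mixture
        assert np.allclose(means, 1.0, atol=0.01)

    def test_invalid_mixtures_rejected(self, small_cfg):
        with pytest.raises(ConfigurationError):
            gen_streetview_counts(2, {"vegetation": -0.5, "sky": 1.5},
                                  small_cfg)
        with pytest.raises(ConfigurationError):
            gen_streetview_counts(2, {"vegetation": 0.6}, small_cfg)

    def test_void_fraction_leaves_unlabeled_pixels(self, small_cfg):
        mix = np.full(len(CLASSES), 1 / len(CLASSES))
        table = gen_streetview_counts(20, mix, small_cfg, void_fraction=0.1)
        sums = table[list(CLASSES)].sum(axis=1)
        assert (sums < small_cfg.pixels_per_image).all()
        assert sums.mean() == pytest.approx(900, rel=0.05)


class TestCityPanel:
    def test_noiseless_panel_exactly_linear(self):
        cfg = SimulationConfig(noise_sd=0.0, seed=3,
                               planted_beta={"SE": 0.5, "NDVI": 0.3})
        panel, truth = gen_city_panel(cfg, n_zones=100)
        recon = cfg.intercept + 0.5 * panel["SE"] + 0.3 * panel["NDVI"]
        assert np.allclose(panel["P1"], recon, atol=1e-12)
        assert truth["active"] == ["SE", "NDVI"]

    def test_same_seed_identical_panel(self):
        cfg = SimulationConfig(seed=9)
        a, _ = gen_city_panel(cfg)
        b, _ = gen_city_panel(cfg)
        assert a.equals(b)

    def test_ols_on_true_active_set_recovers_beta(self):
        # sampling-variance oracle: mean estimate over 50 seeds
        import statsmodels.api as sm
        errs = []
        for seed in range(50):
            cfg = SimulationConfig(seed=seed, noise_sd=0.05,
                                   planted_beta={"SE": 0.5, "NDVI": 0.3})
            panel, _ = gen_city_panel(cfg, n_zones=500)
            X = sm.add_constant(panel[["SE", "NDVI"]].to_numpy())
            fit = sm.OLS(panel["P1"].to_numpy(), X).fit()
            errs.append(fit.params[1:] - np.array([0.5, 0.3]))
        mean_err = np.abs(np.mean(errs, axis=0))
        assert np.all(mean_err < 0.02)
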