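import dataclasses

import numpy as np
import pandas as pd
import pytest

from plotspec import (
    SceneConfig,
    build_design,
    read_scene,
    render_scene,
    simulate_ground_truth,
    simulate_scene,
    simulate_vi_yield_trial,
    write_scene,
)
from plotspec.errors import InvalidConfigError, StageError
from tests.conftest import COARSE_GSD, noiseless


class TestDesign:
    def test_default_design_has_36_plots_of_16_m2(self, coarse_config):
        layout = build_design(coarse_config)
        assert len(layout) == 36
        areas = [g.area for g in layout.frame.geometry]
        assert np.allclose(areas, 16.0)

    def test_degenerate_single_plot_grid(self):
        cfg = SceneConfig(n_levels=(100.0,), varieties=1, replicates=1, gsd=COARSE_GSD)
        assert len(build_design(cfg)) == 1

    def test_partial_grid_counts_by_enumeration(self):
        cfg = SceneConfig(n_levels=(0.0, 200.0), varieties=3, replicates=3, gsd=COARSE_GSD)
        layout = build_design(cfg)
        assert len(layout) == 18
        assert layout.frame.groupby("n_level").size().eq(9).all()
        assert layout.frame.groupby("variety").size().eq(6).all()

    def test_plots_pairwise_disjoint(self, coarse_config):
        geoms = list(build_design(coarse_config).frame.geometry)
        for i in range(len(geoms)):
            for j in range(i + 1, len(geoms)):
                assert not geoms[i].intersects(geoms[j])

    def test_invalid_dimensions_rejected(self):
        with pytest.raises(InvalidConfigError):
            SceneConfig(plot_size=(0.0, 8.0))
        with pytest.raises(InvalidConfigError):
            SceneConfig(gsd=-0.01)


class TestGroundTruth:
    def test_zero_yield_noise_is_exactly_linear_in_vigor(self, coarse_config):
        cfg = dataclasses.replace(
            coarse_config, yield_model={"intercept": 2800.0, "slope": 7000.0, "noise_sd": 0.0}
        )
        truth = simulate_ground_truth(build_design(cfg), cfg, seed=3)
        expected = 2800.0 + 7000.0 * truth.plots["vigor"]
        np.testing.assert_allclose(truth.plots["yield_kg_ha"], expected, rtol=1e-12)

    def test_same_seed_reproduces_ground_truth(self, coarse_config):
        layout = build_design(coarse_config)
        a = simulate_ground_truth(layout, coarse_config, seed=5)
        b = simulate_ground_truth(layout, coarse_config, seed=5)
        pd.testing.assert_frame_equal(a.plots, b.plots)
        pd.testing.assert_frame_equal(a.cover, b.cover)

    def test_mean_yield_increases_with_n_rate(self, coarse_config):
        # Monte-Carlo check of the built-in monotone vigor model
        layout = build_design(coarse_config)
        n0, n3 = [], []
        for seed in range(200):
            truth = simulate_ground_truth(layout, coarse_config, seed=seed)
            by_n = truth.plots.groupby("n_level")["yield_kg_ha"].mean()
            n0.append(by_n.loc[0.0])
            n3.append(by_n.loc[300.0])
        assert np.mean(n3) > np.mean(n0)

    def test_negative_noise_sd_rejected(self, coarse_config):
        with pytest.raises(InvalidConfigError):
            dataclasses.replace(
                coarse_config, yield_model={"intercept": 1.0, "slope": 1.0, "noise_sd": -1.0}
            )


class TestRender:
    def test_unknown_stage_rejected(self, coarse_config):
        truth = simulate_ground_truth(build_design(coarse_config), coarse_config, seed=1)
        with pytest.raises(StageError):
            render_scene(truth, "nope", coarse_config, seed=1)

    def test_pure_panel_pixel_inverts_elm_exactly(self, coarse_config):
        # DN = R / a: reflectance 0.5 with a = 0.00025 must give DN 2000
        cfg = noiseless(
            coarse_config,
            elm_true_slopes=(2.5e-4,) * 5,
            panel_reflectances=((0.5,) * 5,),
        )
        truth = simulate_ground_truth(build_design(cfg), cfg, seed=1)
        render = render_scene(truth, "J", cfg, seed=1)
        from plotspec.geo import pixel_center_mask

        sel = pixel_center_mask(cfg.transform, cfg.raster_shape, render.panels.polygons[0])
        np.testing.assert_allclose(render.dn.data[:, sel], 2000.0, rtol=1e-12)

    def test_zero_cover_renders_pure_soil(self, coarse_config):
        cfg = noiseless(
            coarse_config,
            cover_params={s: (0.0, 0.0) for s in coarse_config.stages},
        )
        truth = simulate_ground_truth(build_design(cfg), cfg, seed=1)
        render = render_scene(truth, "J", cfg, seed=1, keep_true_reflectance=True)
        # mask out panel footprints, check the rest equals the soil spectrum
        from plotspec.geo import pixel_center_mask

        panel_px = np.zeros(cfg.raster_shape, dtype=bool)
        for poly in render.panels.polygons:
            panel_px |= pixel_center_mask(cfg.transform, cfg.raster_shape, poly)
        for b, soil in enumerate(cfg.soil_spectrum):
            np.testing.assert_allclose(render.true_reflectance.data[b][~panel_px], soil, atol=1e-6)
        assert not render.true_mask.mask.any()

    def test_linear_mixture_weights(self):
        # cover 0.4, canopy red 0.05, soil red 0.30 -> 0.4*0.05 + 0.6*0.30 = 0.20
        assert np.isclose(0.4 * 0.05 + 0.6 * 0.30, 0.20)
        cfg = SceneConfig(gsd=COARSE_GSD)
        v = 0.6
        canopy = cfg.canopy_spectrum(v)
        mixed = 0.4 * canopy + 0.6 * np.asarray(cfg.soil_spectrum)
        np.testing.assert_allclose(
            mixed, [0.4 * c + 0.6 * s for c, s in zip(canopy, cfg.soil_spectrum)]
        )

    def test_rendered_ranges_and_determinism(self, coarse_scene, coarse_config):
        for stage, render in coarse_scene.stages.items():
            dn = render.dn.data
            assert dn.dtype == np.uint16
            assert dn.min() >= 0 and dn.max() <= 65535
        truth = coarse_scene.truth
        a = render_scene(truth, "H", coarse_config, seed=99)
        b = render_scene(truth, "H", coarse_config, seed=99)
        np.testing.assert_array_equal(a.dn.data, b.dn.data)
        np.testing.assert_array_equal(a.true_mask.mask, b.true_mask.mask)

    def test_reflectance_bounded(self, coarse_scene):
        refl = coarse_scene.stages["LGF"].true_reflectance.data
        assert float(refl.min()) >= 0.0 and float(refl.max()) <= 1.0


class TestSceneInvariants:
    def test_plot_mean_nir_correlates_with_yield_across_seeds(self, coarse_config):
        # structural target of the generator: canopy vigor couples NIR and yield
        layout = build_design(coarse_config)
        rs = []
        for seed in range(25):
            truth = simulate_ground_truth(layout, coarse_config, seed=seed)
            nir = truth.plot_mean_reflectance("H", coarse_config.soil_spectrum)["nir"]
            r = np.corrcoef(nir, truth.plots["yield_kg_ha"])[0, 1]
            rs.append(r)
        assert all(r > 0.5 for r in rs)

    def test_scene_roundtrip_bit_identical(self, tmp_path, coarse_config):
        cfg = dataclasses.replace(coarse_config, stages=("J", "LGF"),
                                  cover_params=coarse_config.cover_params)
        bundle = simulate_scene(cfg)
        write_scene(bundle, tmp_path / "scene")
        back = read_scene(tmp_path / "scene")
        assert len(back.layout) == 36
        assert set(back.layout.frame.columns) >= {"n_level", "variety", "replicate"}
        for stage in cfg.stages:
            np.testing.assert_array_equal(
                back.stages[stage].dn.data, bundle.stages[stage].dn.data
            )
        assert back.stages["J"].panels.reflectances.shape == (4, 5)
        pd.testing.assert_frame_equal(back.truth.plots, bundle.truth.plots)


class TestViYieldTrial:
    def test_population_r2_controls_noise(self):
        vi, traits, sigma = simulate_vi_yield_trial(seed=0, population_r2=0.85)
        assert len(vi) == 36 and len(traits) == 36
        # analytic sigma: higher target R2 -> less noise
        _, _, sigma_tight = simulate_vi_yield_trial(seed=0, population_r2=0.95)
        assert sigma_tight < sigma

    def test_invalid_r2_rejected(self):
        with pytest.raises(InvalidConfigError):
            simulate_vi_yield_trial(seed=0, population_r2=1.5)

    def test_empirical_r2_matches_target_at_large_n(self):
        # with many replicates the realized R2 approaches the analytic target
        vi, traits, _ = simulate_vi_yield_trial(seed=1, population_r2=0.85, replicates=300)
        r = np.corrcoef(vi["value"], traits["yield_kg_ha"])[0, 1]
        assert abs(r**2 - 0.85) < 0.03
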