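"""Calibrated synthetic-study generator: presets, case draws, renderers,
phantom scenes, and statistical recovery of the generative parameters."""

import numpy as np
import pytest
from scipy import stats as sps

from lyticgray import (SceneConfig, binormal_auc, compute_gray_features,
                       extract_roi, generate_group_cases,
                       generate_radiograph_scene, render_roi_image,
                       simulate_feature_auc, study_presets)
from lyticgray.imaging import BoneClass, Group
from lyticgray.synthetic import derive_seed, ground_truth_roi, scene_for_case


class TestPresets:
    def test_stratum_sizes(self):
        p = study_presets()
        assert {k: v.n_cases for k, v in p.items()} == {
            "MM1": 31, "OL1": 35, "MM2": 36, "OL2": 41}

    def test_calibration_cells(self):
        p = study_presets()
        assert p["MM2"].mgl_mean == 1593.21
        assert p["OL2"].sdgl_mean == 270.66
        assert p["OL2"].sdgl_sd == 16.80
        assert p["MM1"].cvgl_mean == 15.02

    def test_group_and_bone_mapping(self):
        p = study_presets()
        assert p["MM1"].group is Group.MM and p["MM1"].bone_class is BoneClass.NONFLAT
        assert p["OL2"].group is Group.OL and p["OL2"].bone_class is BoneClass.FLAT


class TestGroupCases:
    def test_seed_determinism(self):
        p = study_presets()["MM2"]
        np.testing.assert_array_equal(generate_group_cases(p, 7), generate_group_cases(p, 7))
        assert not np.array_equal(generate_group_cases(p, 7), generate_group_cases(p, 8))

    def test_zero_cases_gives_empty(self):
        from dataclasses import replace
        p = replace(study_presets()["MM2"], n_cases=0)
        assert generate_group_cases(p, 1).shape == (0, 3)

    def test_large_sample_mean_recovery(self):
        """Law of large numbers at n=10000: mean within 3 standard errors."""
        from dataclasses import replace
        p = replace(study_presets()["MM2"], n_cases=10_000)
        cases = generate_group_cases(p, 42)
        se = p.mgl_sd / np.sqrt(10_000)
        assert abs(cases[:, 0].mean() - p.mgl_mean) < 3 * se
        se_sd = p.sdgl_sd / np.sqrt(10_000)
        assert abs(cases[:, 1].mean() - p.sdgl_mean) < 3 * se_sd

    def test_cvgl_is_derived_ratio(self):
        cases = generate_group_cases(study_presets()["OL1"], 3)
        np.testing.assert_allclose(cases[:, 2], cases[:, 1] / cases[:, 0] * 100.0, rtol=1e-12)


class TestRenderROI:
    def test_zero_spread_gives_constant(self):
        img = render_roi_image(1500.4, 0.0, seed=1)
        assert np.all(img.pixels == 1500)

    def test_seed_determinism(self):
        a = render_roi_image(1600.0, 250.0, seed=9)
        b = render_roi_image(1600.0, 250.0, seed=9)
        np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_feature_recovery_within_sampling_error(self):
        """40x50 ROI at study scale: MGL within 3*sd/sqrt(2000) of target."""
        mgl, sdgl = 1593.21, 248.12
        img = render_roi_image(mgl, sdgl, height=50, width=40, seed=11)
        f = compute_gray_features(img.pixels.astype(float))
        assert abs(f.mgl - mgl) < 3 * sdgl / np.sqrt(2000)
        assert abs(f.sdgl - sdgl) < 3 * sdgl / np.sqrt(2 * 1999) + 0.5  # +rounding

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            render_roi_image(0.0, 10.0)
        with pytest.raises(ValueError):
            render_roi_image(1000.0, 10.0, height=0)


class TestScene:
    def test_noiseless_scene_is_piecewise_constant(self):
        cfg = SceneConfig(gradient_amplitude=0.0, noise_sd=0.0, lesion_sdgl=0.0,
                          lesion_mgl=1600.0, seed=0)
        img, roi = generate_radiograph_scene(cfg)
        assert set(np.unique(img.pixels)) == {900, 1600, 2400}
        sub = extract_roi(img, roi)
        assert np.all(sub.pixels == 1600)

    def test_lesion_darker_than_band(self):
        img, roi = generate_radiograph_scene(SceneConfig(seed=4))
        sub = extract_roi(img, roi)
        band = img.pixels[20:24, :].astype(float)  # band rows away from lesion
        assert sub.pixels.mean() < band.mean()

    def test_seed_determinism(self):
        a, _ = generate_radiograph_scene(SceneConfig(seed=5))
        b, _ = generate_radiograph_scene(SceneConfig(seed=5))
        np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_ellipse_outside_image_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            SceneConfig(lesion_center=(5, 64))

    def test_roi_fits_inside_lesion(self):
        cfg = SceneConfig()
        roi = ground_truth_roi(cfg)
        assert (roi.width, roi.height) == (40, 50)
        with pytest.raises(ValueError, match="does not fit"):
            ground_truth_roi(SceneConfig(lesion_axes=(20, 15), lesion_center=(64, 64)))

    def test_bright_case_raises_band(self):
        cfg = scene_for_case(2500.0, 200.0, seed=0)
        assert cfg.band_level > 2500.0
        generate_radiograph_scene(cfg)  # must validate and render

    def test_end_to_end_feature_recovery(self):
        """Scene -> ROI extraction -> features recovers the lesion targets."""
        mgl, sdgl = 1700.0, 250.0
        cfg = scene_for_case(mgl, sdgl, seed=21)
        img, roi = generate_radiograph_scene(cfg)
        f = compute_gray_features(extract_roi(img, roi).pixels.astype(float))
        assert abs(f.mgl - mgl) < 3 * sdgl / np.sqrt(2000)
        assert abs(f.sdgl - sdgl) < 3 * sdgl / np.sqrt(2 * 1999) + 0.5


class TestStatisticalRecovery:
    def test_group_mean_unbiasedness_over_replicate_studies(self):
        """200 replicate feature-level studies: the per-stratum mean of MGL
        and SDGL is unbiased for the preset mean (t-test, alpha=0.01)."""
        presets = study_presets()
        for label, p in presets.items():
            means_mgl = []
            means_sdgl = []
            for rep in range(200):
                cases = generate_group_cases(p, derive_seed(1234, "rec", rep))
                means_mgl.append(cases[:, 0].mean())
                means_sdgl.append(cases[:, 1].mean())
            for vals, target in ((means_mgl, p.mgl_mean), (means_sdgl, p.sdgl_mean)):
                t, pval = sps.ttest_1samp(vals, target)
                assert pval > 0.01, f"{label}: bias detected (t={t:.2f}, p={pval:.4f})"

    def test_rendered_pipeline_recovery(self):
        """Rendered ROIs measured by the feature extractor (no filtering)
        recover case parameters without material bias across 30 cases."""
        rng_cases = generate_group_cases(study_presets()["MM2"], 77)[:30]
        err_mgl = []
        for i, (mgl, sdgl, _) in enumerate(rng_cases):
            img = render_roi_image(mgl, sdgl, seed=derive_seed(77, "px", i))
            f = compute_gray_features(img.pixels.astype(float))
            err_mgl.append(f.mgl - mgl)
        se = np.std(err_mgl, ddof=1) / np.sqrt(len(err_mgl))
        assert abs(np.mean(err_mgl)) < 3 * se + 0.05

    def test_simulated_auc_matches_binormal_closed_form(self):
        """Mean Monte Carlo AUC equals the binormal value within 3 MC SEs."""
        p = study_presets()
        for feature, pos, neg in (("mgl", p["OL2"], p["MM2"]),
                                  ("sdgl", p["OL2"], p["MM2"]),
                                  ("cvgl", p["OL1"], p["MM1"])):
            aucs = simulate_feature_auc(p[pos.label], p[neg.label], feature,
                                        n_replicates=400, seed=5)
            target = binormal_auc(getattr(pos, f"{feature}_mean"), getattr(pos, f"{feature}_sd"),
                                  getattr(neg, f"{feature}_mean"), getattr(neg, f"{feature}_sd"))
            mc_se = aucs.std(ddof=1) / np.sqrt(aucs.size)
            assert abs(aucs.mean() - target) < 3 * mc_se + 1e-3, feature
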