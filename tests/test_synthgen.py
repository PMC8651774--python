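"""Generator contracts: sampling moments, stress scaling, rendering truth."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from rbcbiophys.segmentation import segment_frame
from rbcbiophys.synthgen import (
    DEFAULT_PROFILES,
    CellShape,
    ClassProfile,
    GroundTruthRecord,
    SceneConfig,
    StressLevel,
    apply_stress,
    render_pair,
    sample_population,
    simulate_scene,
)


def _dummy_records(n, area=100.0):
    shape = CellShape(a=1.0, b=1.0, phi=0.0, eps=0.0)
    return [
        GroundTruthRecord(
            cell_id=i,
            true_diameter=2 * np.sqrt(area / np.pi),
            true_axis_ratio=1.0,
            true_circularity=1.0,
            true_area_pre=area,
            shape=shape,
        )
        for i in range(n)
    ]


class TestSamplePopulation:
    def test_empty(self):
        assert sample_population(DEFAULT_PROFILES["healthy"], 0, seed=1) == []

    def test_zero_variance_degenerate(self):
        profile = ClassProfile("x", diameter_mean=7.5, diameter_sd=0.0,
                               axis_ratio_sd=0.0, circularity_sd=0.0)
        recs = sample_population(profile, 5, seed=1)
        assert len(recs) == 5
        assert all(r.true_diameter == 7.5 for r in recs)

    def test_negative_n_raises(self):
        with pytest.raises(ValueError):
            sample_population(DEFAULT_PROFILES["healthy"], -1, seed=1)

    def test_invalid_profile_raises(self):
        with pytest.raises(ValueError):
            ClassProfile("bad", diameter_mean=-1.0)
        with pytest.raises(ValueError):
            ClassProfile("bad", axis_ratio_mean=0.9)

    def test_moment_recovery_large_n(self):
        # law of large numbers: sample mean within 4·sd/√n of the profile mean
        profile = DEFAULT_PROFILES["healthy"]
        n = 10_000
        recs = sample_population(profile, n, seed=1)
        d = np.array([r.true_diameter for r in recs])
        assert abs(d.mean() - profile.diameter_mean) < 4 * profile.diameter_sd / np.sqrt(n)
        q = np.array([r.true_axis_ratio for r in recs])
        # axis-ratio truth is the caliper ratio of the realized boundary; the
        # undulation adds a small positive offset, so allow it on top of the SE
        assert q.mean() == pytest.approx(profile.axis_ratio_mean, abs=0.03)
        c = np.array([r.true_circularity for r in recs])
        assert c.mean() == pytest.approx(profile.circularity_mean, abs=0.01)

    def test_axis_ratio_floor_and_area_consistency(self):
        recs = sample_population(DEFAULT_PROFILES["MF"], 200, seed=3)
        assert all(r.true_axis_ratio >= 1.0 for r in recs)
        for r in recs:
            assert r.true_area_pre == pytest.approx(np.pi * r.true_diameter**2 / 4, rel=1e-9)

    def test_deterministic_given_seed(self):
        a = sample_population(DEFAULT_PROFILES["healthy"], 20, seed=9)
        b = sample_population(DEFAULT_PROFILES["healthy"], 20, seed=9)
        assert [r.true_diameter for r in a] == [r.true_diameter for r in b]
        assert [r.true_circularity for r in a] == [r.true_circularity for r in b]


class TestApplyStress:
    def test_none_level_identity(self):
        recs = apply_stress(_dummy_records(10), DEFAULT_PROFILES["healthy"], "none", seed=1)
        assert all(r.true_dr == 1.0 for r in recs)
        assert all(r.true_area_post == r.true_area_pre for r in recs)

    def test_deterministic_dr_area(self):
        # dr 1.194 with zero spread: 100 µm² → 100·1.194² = 142.5636 µm²
        profile = ClassProfile("x", dr_low_mean=1.194, dr_low_sd=0.0)
        recs = apply_stress(_dummy_records(1, area=100.0), profile, "low", seed=1)
        assert recs[0].true_dr == 1.194
        assert recs[0].true_area_post == pytest.approx(142.5636, abs=1e-9)

    def test_high_stress_moment_recovery(self):
        # printed high-stress calibration: mean 1.241, σ 0.033, n = 2362
        profile = DEFAULT_PROFILES["healthy"]
        n = 2362
        recs = apply_stress(_dummy_records(n), profile, "high", seed=7)
        drs = np.array([r.true_dr for r in recs])
        assert abs(drs.mean() - 1.241) < 4 * 0.033 / np.sqrt(n)

    def test_dr_area_identity_invariant(self):
        recs = apply_stress(_dummy_records(50), DEFAULT_PROFILES["healthy"], "high", seed=2)
        for r in recs:
            assert r.true_dr == pytest.approx(np.sqrt(r.true_area_post / r.true_area_pre), abs=1e-12)


class TestRenderPair:
    def test_empty_field_uniform_background(self):
        config = SceneConfig(field_width=50, field_height=50, n_cells=0,
                             noise_sd=0.0, illumination_gradient=0.0, seed=1)
        pre, post, truth = render_pair(config, [])
        assert len(truth) == 0
        assert len(np.unique(pre.pixels)) == 1
        assert np.array_equal(pre.pixels, post.pixels)

    def test_single_cell_area_ratio_matches_dr_squared(self):
        profile = ClassProfile("x", diameter_sd=0.0, axis_ratio_mean=1.0,
                               axis_ratio_sd=0.0, circularity_mean=1.0,
                               circularity_sd=0.0, dr_mean=1.241, dr_sd=0.0)
        config = SceneConfig(field_width=50, field_height=50, n_cells=1,
                             stacking_fraction=0.0, noise_sd=0.0,
                             illumination_gradient=0.0, border_margin_um=8, seed=4)
        recs = apply_stress(sample_population(profile, 1, seed=1), profile, "high", seed=1)
        pre, post, truth = render_pair(config, recs)
        # pixel-count oracle on the rendered masks
        a_pre = np.sum(pre.pixels < 180)
        a_post = np.sum(post.pixels < 180)
        assert a_post / a_pre == pytest.approx(1.241**2, rel=0.02)

    def test_determinism_bit_identical(self):
        profile = DEFAULT_PROFILES["healthy"]
        config = SceneConfig(field_width=100, field_height=100, n_cells=20, seed=11)
        pre1, post1, t1 = simulate_scene(profile, config)
        pre2, post2, t2 = simulate_scene(profile, config)
        assert np.array_equal(pre1.pixels, pre2.pixels)
        assert np.array_equal(post1.pixels, post2.pixels)
        pd.testing.assert_frame_equal(t1, t2)

    def test_truth_record_count_conserved(self, noisy_scene):
        config, pre, post, truth = noisy_scene
        assert len(truth) == config.n_cells

    def test_raster_too_small_raises(self):
        profile = ClassProfile("x", diameter_mean=30.0, diameter_sd=0.0)
        recs = sample_population(profile, 1, seed=1)
        config = SceneConfig(field_width=25, field_height=25, n_cells=1, seed=1)
        with pytest.raises(ValueError, match="larger than|smaller"):
            render_pair(config, recs)

    def test_identical_placement_pre_post(self, clean_scene):
        # cells are immobilized: the dark-pixel centroid barely moves
        _, pre, post, truth = clean_scene
        assert truth["centroid_row_um"].notna().all()

    def test_calibration_segmented_areas_within_5pct(self, clean_scene):
        # measuring a noise-free scene recovers true per-cell areas within 5%
        from scipy.spatial import cKDTree

        config, pre, post, truth = clean_scene
        kept, _ = segment_frame(pre)
        assert kept, "segmentation found no cells"
        scale = pre.pixel_scale
        cent = np.array([r.centroid for r in kept]) * scale
        tree = cKDTree(truth[["centroid_row_um", "centroid_col_um"]].to_numpy())
        dist, idx = tree.query(cent)
        assert dist.max() < 2.0
        true_area = truth["true_area_pre_um2"].to_numpy()[idx]
        meas_area = np.array([r.area_px for r in kept]) * scale**2
        keep = truth["true_diameter_um"].to_numpy()[idx] >= 5.0
        rel = np.abs(meas_area[keep] - true_area[keep]) / true_area[keep]
        assert rel.max() < 0.05


def test_stress_level_roundtrip_and_profile_serialization(tmp_path):
    p = DEFAULT_PROFILES["Thal"]
    p2 = ClassProfile.from_dict(p.to_dict())
    assert p2 == p
    assert StressLevel("low") is StressLevel.LOW


def test_save_scene_writes_files(tmp_path, noisy_scene):
    from rbcbiophys.synthgen import save_scene

    config, pre, post, truth = noisy_scene
    paths = save_scene(tmp_path / "scene", pre, post, truth, config,
                       DEFAULT_PROFILES["healthy"])
    for key in ("pre", "post", "truth", "config"):
        assert paths[key].exists()
    loaded = pd.read_csv(paths["truth"])
    assert len(loaded) == len(truth)
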