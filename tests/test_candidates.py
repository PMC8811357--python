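"""Stage-2 features, voxel classifier, probability thresholding and the FROC sweep."""

from dataclasses import replace

import numpy as np
import pytest

from cmbselect.candidates import (
    FEATURE_NAMES,
    CandidateModel,
    FeatureConfig,
    assemble_features,
    blobness_map,
    clahe_map,
    exp_intensity,
    frst_map,
    log_map,
    predict_probability,
    sample_training_voxels,
    sweep_th_prob,
    threshold_candidates,
    train_voxel_classifier,
)
from cmbselect.phantom import PhantomSpec, generate_phantom, rasterize_ellipsoid
from cmbselect.preprocess import VolumeImage, standardize_intensity


def _dark_disc_volume(radius_vox=3, contrast=0.3, grid=(48, 48, 3)):
    sphere = rasterize_ellipsoid(
        (24, 24, 1), (radius_vox, radius_vox, 0.6), grid, (1, 1, 1)
    )
    vox = np.full(grid, 100.0)
    vox[sphere] = 100.0 * (1 - contrast)
    return VolumeImage.from_voxel_size(vox, (1, 1, 1)), sphere


class TestClahe:
    def test_bounded_output(self):
        rng = np.random.default_rng(0)
        vol = VolumeImage.from_voxel_size(rng.normal(50, 20, (32, 32, 4)), (1, 1, 1))
        out = clahe_map(vol, np.ones(vol.shape, bool))
        assert out.min() >= 0 and out.max() <= 1

    def test_constant_volume_degenerate_path(self):
        vol = VolumeImage.from_voxel_size(np.full((16, 16, 2), 5.0), (1, 1, 1))
        with pytest.warns(UserWarning):
            out = clahe_map(vol, np.ones(vol.shape, bool))
        assert np.all(out == 0)

    def test_low_contrast_sphere_contrast_increases(self):
        # dark disc on a slow background ramp: the disc occupies a small
        # fraction of the global intensity range, so adaptive equalization
        # should amplify its local contrast
        grid = (48, 48, 3)
        ramp = np.tile(np.linspace(60, 140, 48)[:, None, None], (1, 48, 3))
        sphere = rasterize_ellipsoid((24, 24, 1), (4, 4, 0.6), grid, (1, 1, 1))
        ring = rasterize_ellipsoid((24, 24, 1), (8, 8, 0.6), grid, (1, 1, 1)) & ~sphere
        vox = ramp.copy()
        vox[sphere] -= 8.0
        vol = VolumeImage.from_voxel_size(vox, (1, 1, 1))
        mask = np.ones(grid, bool)
        scaled = (vox - vox.min()) / np.ptp(vox)
        out = clahe_map(vol, mask)
        before = scaled[ring].mean() - scaled[sphere].mean()
        after = out[ring].mean() - out[sphere].mean()
        assert after > before > 0


class TestExpIntensity:
    def test_closed_forms_and_monotonicity(self):
        vox = np.array([[[0.0, -1.0, 1.0, -2.0]]])
        out = exp_intensity(VolumeImage.from_voxel_size(vox, (1, 1, 1)), p=1.0)
        assert out[0, 0, 0] == pytest.approx(1.0)
        assert out[0, 0, 1] == pytest.approx(np.exp(-1), rel=1e-6)
        # darker voxel -> strictly smaller feature
        assert out[0, 0, 3] < out[0, 0, 1] < out[0, 0, 0] < out[0, 0, 2]

    def test_overflow_clipped_with_warning(self):
        vox = np.full((2, 2, 1), 100.0)
        with pytest.warns(UserWarning, match="clip"):
            out = exp_intensity(VolumeImage.from_voxel_size(vox, (1, 1, 1)), p=1.0)
        assert np.isfinite(out).all()


class TestFrst:
    def test_constant_image_zero(self):
        vol = VolumeImage.from_voxel_size(np.full((32, 32, 2), 9.0), (1, 1, 1))
        out = frst_map(vol, np.ones(vol.shape, bool))
        assert np.all(out == 0)

    def test_dark_disc_peak_near_center(self):
        vol, _ = _dark_disc_volume(radius_vox=3)
        out = frst_map(vol, np.ones(vol.shape, bool), radii=(2, 3, 4))
        peak = np.unravel_index(np.argmax(out[:, :, 1]), (48, 48))
        assert abs(peak[0] - 24) <= 1 and abs(peak[1] - 24) <= 1

    def test_dark_bar_weaker_than_disc(self):
        grid = (48, 48, 3)
        bar = np.full(grid, 100.0)
        bar[10:38, 22:25, 1] = 70.0  # elongated dark bar, same contrast
        disc_vol, _ = _dark_disc_volume(radius_vox=3)
        mask = np.ones(grid, bool)
        out_bar = frst_map(VolumeImage.from_voxel_size(bar, (1, 1, 1)), mask)
        out_disc = frst_map(disc_vol, mask)
        assert out_bar[24, 23, 1] < out_disc[24, 24, 1]


class TestBlobnessAndLog:
    def test_constants_map_to_zero(self):
        # discrete truncated kernels leave a residual ~1e-4 of the intensity
        vol = VolumeImage.from_voxel_size(np.full((16, 16, 2), 4.0), (1, 1, 1))
        assert np.allclose(blobness_map(vol), 0, atol=1e-8)
        assert np.abs(log_map(vol)).max() < 1e-3 * 4.0

    def test_ramp_log_near_zero(self):
        ramp = np.tile(np.linspace(0, 10, 32)[:, None, None], (1, 32, 2))
        out = log_map(VolumeImage.from_voxel_size(ramp, (1, 1, 1)))
        interior = np.abs(out[8:24, 8:24, :]).max()
        # second derivative of a linear ramp vanishes up to kernel truncation
        assert interior < 1e-3 * 10.0

    def test_dark_sphere_blobness_negative_at_center(self):
        vol, _ = _dark_disc_volume(radius_vox=2)
        out = blobness_map(vol, sigma=1.5)
        assert out[24, 24, 1] < -1.0
        assert abs(out[5, 5, 1]) < 0.5

    def test_blobness_high_pass_sums_near_zero(self):
        rng = np.random.default_rng(7)
        vol = VolumeImage.from_voxel_size(rng.normal(0, 1, (64, 64, 1)), (1, 1, 1))
        out = blobness_map(vol, sigma=1.5)
        assert abs(out.sum()) < 0.01 * np.abs(vol.voxels).sum()

    def test_dark_sphere_log_extremal_at_center(self):
        vol, _ = _dark_disc_volume(radius_vox=2)
        out = log_map(vol, sigma=1.5)
        sl = out[:, :, 1]
        assert np.unravel_index(np.argmax(sl), sl.shape) == (24, 24)


class TestAssemble:
    def test_normalization_and_determinism(self, phantom_subject, cfg):
        s = phantom_subject
        std = standardize_intensity(s.image, s.brain_mask)
        a = assemble_features(std, s.brain_mask, cfg.features)
        b = assemble_features(std, s.brain_mask, cfg.features)
        for name in FEATURE_NAMES:
            peak = np.abs(a.maps[name]).max()
            assert peak == pytest.approx(1.0) or peak == 0.0
            assert np.array_equal(a.maps[name], b.maps[name])

    def test_cmb_center_vector_separates_from_background(self, phantom_subject, cfg):
        s = phantom_subject
        std = standardize_intensity(s.image, s.brain_mask)
        stack = assemble_features(std, s.brain_mask, cfg.features)
        bg = s.brain_mask & (s.cmb_truth == 0) & ~s.mimic_mask
        X_bg = stack.matrix(bg)
        med = np.median(X_bg, axis=0)
        iqr = np.percentile(X_bg, 75, axis=0) - np.percentile(X_bg, 25, axis=0)
        # centroid voxel of the first CMB
        idx = np.argwhere(s.cmb_truth == 1)
        center = tuple(np.round(idx.mean(axis=0)).astype(int))
        vec = np.array([stack.maps[n][center] for n in FEATURE_NAMES])
        separated = np.abs(vec - med) >= iqr
        assert separated.sum() >= 4

    def test_nonfinite_feature_rejected(self, cfg):
        vox = np.full((33, 33, 4), 1.0)
        vox[0, 0, 0] = np.nan
        vol = VolumeImage.from_voxel_size(vox, (1, 1, 1))
        mask = np.ones(vol.shape, bool)
        with pytest.raises(ValueError, match="intensity"):
            assemble_features(vol, mask, cfg.features)


class TestSampling:
    def _tiny_stack(self, shape=(10, 10, 2)):
        rng = np.random.default_rng(0)
        maps = {n: rng.normal(size=shape) for n in FEATURE_NAMES}
        from cmbselect.candidates import VoxelFeatureStack

        return VoxelFeatureStack(maps=maps)

    def test_row_count_arithmetic(self):
        stack = self._tiny_stack()
        truth = np.zeros((10, 10, 2), dtype=int)
        truth.ravel()[:100] = 1
        brain = np.ones((10, 10, 2), bool)
        X, y = sample_training_voxels(stack, truth, brain, neg_pos_ratio=1, seed=0)
        assert len(X) == 200 and (y == 1).sum() == 100

    def test_seed_reproducibility(self):
        stack = self._tiny_stack()
        truth = np.zeros((10, 10, 2), dtype=int)
        truth[0, 0, 0] = 1
        brain = np.ones((10, 10, 2), bool)
        X1, y1 = sample_training_voxels(stack, truth, brain, seed=3)
        X2, y2 = sample_training_voxels(stack, truth, brain, seed=3)
        assert np.array_equal(X1, X2) and np.array_equal(y1, y2)

    def test_negatives_only_from_brain_mask(self):
        stack = self._tiny_stack()
        truth = np.zeros((10, 10, 2), dtype=int)
        truth[5, 5, 0] = 1
        brain = np.zeros((10, 10, 2), bool)
        brain[4:7, 4:7, :] = True
        # poison out-of-mask voxels: if any were sampled, X would contain 999
        for n in FEATURE_NAMES:
            stack.maps[n][~brain] = 999.0
        stack.maps[FEATURE_NAMES[0]][5, 5, 0] = 0.5
        X, y = sample_training_voxels(stack, truth, brain, neg_pos_ratio=10, seed=1)
        assert not np.any(X == 999.0)

    def test_no_positives_rejected(self):
        stack = self._tiny_stack()
        with pytest.raises(ValueError):
            sample_training_voxels(
                stack, np.zeros((10, 10, 2), int), np.ones((10, 10, 2), bool)
            )


class TestClassifier:
    def test_separable_training_accuracy(self):
        rng = np.random.default_rng(0)
        X0 = rng.normal(0, 0.1, (60, 7))
        X1 = rng.normal(3, 0.1, (60, 7))
        X = np.vstack([X0, X1])
        y = np.array([0] * 60 + [1] * 60)
        model = train_voxel_classifier([(X, y)], seed=0)
        pred = model.estimator.predict(X)
        assert (pred == y).mean() == 1.0
        probs = model.estimator.predict_proba(X)
        assert probs.min() >= 0 and probs.max() <= 1

    def test_single_class_rejected(self):
        X = np.zeros((10, 7))
        with pytest.raises(ValueError):
            train_voxel_classifier([(X, np.zeros(10, int))])

    def test_predict_probability_bounds_and_masking(self, phantom_subject, small_model, cfg):
        s = phantom_subject
        std = standardize_intensity(s.image, s.brain_mask)
        stack = assemble_features(std, s.brain_mask, cfg.features)
        p = predict_probability(small_model, stack, s.brain_mask)
        assert p.min() >= 0 and p.max() <= 1
        assert np.all(p[~s.brain_mask] == 0)

    def test_cmb_centers_scored_above_background(self, phantom_subject, small_model, cfg):
        s = phantom_subject
        std = standardize_intensity(s.image, s.brain_mask)
        stack = assemble_features(std, s.brain_mask, cfg.features)
        p = predict_probability(small_model, stack, s.brain_mask)
        bg = s.brain_mask & (s.cmb_truth == 0) & ~s.mimic_mask
        assert np.median(p[s.cmb_truth > 0]) > np.median(p[bg])

    def test_feature_set_mismatch_rejected(self, small_model):
        from cmbselect.candidates import VoxelFeatureStack

        bad = VoxelFeatureStack(
            maps={"a": np.zeros((4, 4, 2))}, feature_names=("a",)
        )
        with pytest.raises(ValueError, match="feature"):
            predict_probability(small_model, bad, np.ones((4, 4, 2), bool))


class TestThresholdAndSweep:
    def test_extreme_thresholds(self):
        rng = np.random.default_rng(2)
        p = rng.random((8, 8, 2))
        assert not threshold_candidates(p, 1.0).any()
        assert threshold_candidates(p, 0.0).sum() == (p > 0).sum()

    def test_candidate_count_monotone_in_threshold(self):
        rng = np.random.default_rng(3)
        p = rng.random((16, 16, 4))
        counts = [threshold_candidates(p, th).sum() for th in np.linspace(0, 1, 11)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_sweep_grid_and_tpr_monotonicity(self, small_model, small_test_cohort, small_results):
        pairs = [
            (r.probability_map, s.cmb_truth)
            for r, s in zip(small_results, small_test_cohort)
        ]
        rows = sweep_th_prob(small_model, pairs)
        assert len(rows) == 11
        tprs = [r["cluster_tpr"] for r in rows if r["cluster_tpr"] is not None]
        assert all(a >= b - 1e-12 for a, b in zip(tprs, tprs[1:]))
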