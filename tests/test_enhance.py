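"""Patch handling, augmentation, network training/prediction, fold plans."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from petmu.core import ConfigurationError, ValidationError, VoxelVolume
from petmu.enhance import (AugmentRanges, UNetEnhancer, augment, crossval,
                           denormalize, normalize, sample_patches)
from petmu.enhance.model import run_crossval

from conftest import VOXEL_MM


class TestNormalize:
    def test_zero_mean_unit_variance(self, rng):
        v = rng.random((32, 32)) * 7 + 3
        out, stats = normalize(v)
        assert abs(out.mean()) < 1e-6
        assert out.var() == pytest.approx(1.0, abs=1e-6)

    def test_round_trip(self, rng):
        v = rng.random((16, 16))
        out, stats = normalize(v)
        assert np.allclose(denormalize(out, stats), v, rtol=1e-6)

    def test_affine_invariance(self, rng):
        v = rng.random((16, 16))
        a, _ = normalize(v)
        b, _ = normalize(3.5 * v + 2.0)
        assert np.allclose(a, b, atol=1e-10)

    def test_constant_volume_rejected(self):
        with pytest.raises(ValidationError):
            normalize(np.full((8, 8), 5.0))


class TestSamplePatches:
    def test_identical_volumes_give_identical_pairs(self, rng):
        v = rng.random((64, 64))
        xs, ys = sample_patches(v, v, 16, 5, seed=1)
        assert np.array_equal(xs, ys)

    def test_requested_count_and_bounds(self, rng):
        v = rng.random((80, 80))
        xs, ys = sample_patches(v, v, 32, 7, seed=2)
        assert xs.shape == (7, 32, 32)

    def test_deterministic_per_seed(self, rng):
        v = rng.random((64, 64))
        a = sample_patches(v, v, 16, 4, seed=3)[0]
        b = sample_patches(v, v, 16, 4, seed=3)[0]
        assert np.array_equal(a, b)

    def test_body_coverage_rule(self):
        # body occupies the lower-right half; patches should prefer it
        v = np.zeros((64, 64))
        v[32:, 32:] = 0.1
        xs, _ = sample_patches(v, v, 16, 10, seed=4)
        fracs = (xs > 1e-4).reshape(10, -1).mean(axis=1)
        assert (fracs >= 0.5).all()

    def test_volume_smaller_than_patch_rejected(self, rng):
        v = rng.random((8, 8))
        with pytest.raises(ValidationError):
            sample_patches(v, v, 16, 1, seed=0)


class TestAugment:
    def test_zero_ranges_is_identity(self, rng):
        p = rng.random((32, 32))
        a, b = augment(p, p, AugmentRanges(0.0, 0.0), seed=0)
        assert np.array_equal(a, p)

    def test_uniform_patch_values_unchanged_by_zoom(self):
        """Scaling is geometric resampling, not an intensity change."""
        p = np.full((32, 32), 0.096)
        a, _ = augment(p, p, AugmentRanges(0.2, 0.0), seed=5)
        interior = a[8:24, 8:24]
        assert np.allclose(interior, 0.096, rtol=1e-6)

    def test_rotation_round_trip_small_interior_error(self, rng):
        from petmu.enhance.patches import _affine_about_center, _rotation_matrix

        smooth = gaussian_filter(rng.random((48, 48)), 3.0) + 0.5
        theta = np.deg2rad(8.0)
        fwd = _affine_about_center(smooth, _rotation_matrix(2, theta))
        back = _affine_about_center(fwd, _rotation_matrix(2, -theta))
        interior = (slice(10, 38), slice(10, 38))
        rel = np.abs(back[interior] - smooth[interior]) / smooth[interior]
        assert rel.mean() < 0.01

    def test_same_transform_applied_to_both_members(self, rng):
        p = gaussian_filter(rng.random((32, 32)), 2.0)
        q = p * 2.0
        a, b = augment(p, q, AugmentRanges(0.2, 10.0), seed=6)
        assert np.allclose(b, 2.0 * a, atol=1e-10)


def _mu_vol(values):
    return VoxelVolume(np.clip(values, 0, None), VOXEL_MM, "mu_map", 511.0)


@pytest.fixture(scope="module")
def noisy_pair():
    rng = np.random.default_rng(7)
    clean = np.zeros((64, 64))
    clean[16:48, 12:52] = 0.096
    clean[24:40, 24:40] = 0.143
    noisy = np.clip(clean + rng.normal(0, 0.02, clean.shape), 0, None)
    return _mu_vol(noisy), _mu_vol(clean)


def small_enhancer(**kw):
    kw.setdefault("levels", 2)
    kw.setdefault("base_channels", 4)
    kw.setdefault("patch_size", 32)
    kw.setdefault("epochs", 30)
    kw.setdefault("patches_per_volume", 4)
    kw.setdefault("batch_size", 4)
    kw.setdefault("augment_scale", 0.0)
    kw.setdefault("augment_rotation_deg", 0.0)
    kw.setdefault("seed", 0)
    return UNetEnhancer(**kw)


class TestTraining:
    def test_single_pair_overfit_reduces_loss(self, noisy_pair):
        est = small_enhancer(base_channels=8, patch_size=64, epochs=300,
                             patches_per_volume=1, batch_size=1, lr=2e-3)
        est.fit([noisy_pair[0]], [noisy_pair[1]])
        assert est.loss_curve_[-1] < 0.1 * est.loss_curve_[0]

    def test_identity_task_predicts_input(self, noisy_pair):
        est = small_enhancer(epochs=120)
        vol = noisy_pair[1]  # clean target as its own input
        est.fit([vol], [vol])
        pred = est.predict(vol)
        body = vol.values > 0
        rel = np.abs(pred.values[body] - vol.values[body]) / vol.values[body]
        assert rel.mean() < 0.01

    def test_same_seeds_give_identical_loss_curves(self, noisy_pair):
        a = small_enhancer(epochs=5).fit([noisy_pair[0]], [noisy_pair[1]])
        b = small_enhancer(epochs=5).fit([noisy_pair[0]], [noisy_pair[1]])
        assert a.loss_curve_ == b.loss_curve_

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValidationError):
            small_enhancer().fit([], [])


class TestPrediction:
    def test_output_nonnegative_everywhere(self, noisy_pair):
        est = small_enhancer(epochs=10)
        est.fit([noisy_pair[0]], [noisy_pair[1]])
        assert (est.predict(noisy_pair[0]).values >= 0).all()

    def test_tiling_seam_bounded_across_offsets(self, noisy_pair):
        """Predictions from two tiling grids (half-patch vs quarter-patch
        stride) must agree to within 2% of the body-mean mu."""
        est = small_enhancer(epochs=120)
        vol = noisy_pair[1]
        est.fit([vol], [vol])
        a = est.predict(vol, stride=16).values
        b = est.predict(vol, stride=8).values
        body = vol.values > 0
        assert np.abs(a - b)[body].max() < 0.02 * a[body].mean()

    def test_model_save_load_round_trip(self, tmp_path, noisy_pair):
        est = small_enhancer(epochs=5)
        est.fit([noisy_pair[0]], [noisy_pair[1]])
        path = tmp_path / "model.npz"
        est.save(path)
        loaded = UNetEnhancer.load(path)
        a = est.predict(noisy_pair[0]).values
        b = loaded.predict(noisy_pair[0]).values
        assert np.allclose(a, b, atol=1e-6)


class TestCrossval:
    def test_twenty_subjects_five_disjoint_folds_of_four(self):
        plan = crossval(list(range(20)), k=5, seed=0)
        tests = [set(te) for _, te in plan.folds]
        assert all(len(t) == 4 for t in tests)
        for i in range(5):
            for j in range(i + 1, 5):
                assert not tests[i] & tests[j]

    def test_union_of_test_sets_covers_all_subjects(self):
        plan = crossval(list(range(18)), k=5, seed=1)
        union = set()
        for _, te in plan.folds:
            union |= set(te)
        assert union == set(range(18))

    def test_no_test_subject_in_its_own_training_list(self):
        plan = crossval(list(range(11)), k=3, seed=2)
        for tr, te in plan.folds:
            assert not set(tr) & set(te)

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ConfigurationError):
            crossval([1, 2, 3], k=5)

    def test_training_never_sees_test_subjects(self, noisy_pair):
        """Instrumented estimator records which subjects it was fitted on."""
        rng = np.random.default_rng(0)
        inputs, targets = {}, {}
        for i in range(4):
            v = np.clip(noisy_pair[1].values
                        + rng.normal(0, 0.02, (64, 64)), 0, None)
            inputs[i] = _mu_vol(v)
            targets[i] = noisy_pair[1]
        seen = []

        class Spy(UNetEnhancer):
            def fit(self, ins, tars):
                seen.append([id(x) for x in ins])
                return super().fit(ins, tars)

        plan = crossval(list(range(4)), k=2, seed=3)
        recs = run_crossval(inputs, targets, plan,
                            lambda f: Spy(levels=2, base_channels=2,
                                          patch_size=32, epochs=2, seed=f),
                            lambda p, t: 0.0)
        for rec, fitted_ids in zip(recs, seen):
            for sid in rec["test_ids"]:
                assert id(inputs[sid]) not in fitted_ids
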