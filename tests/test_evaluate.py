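"""rME/rMAE metrics, tissue segmentation, isocontours, SUV, reports."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from petmu.core import ValidationError, VoxelVolume
from petmu.evaluate import (build_report, isocontour_lesion, rmae, rme,
                            segment_tissues, suv)
from petmu.phantom import build_phantom, body_phantom_spec

from conftest import VOXEL_MM


def _vol(values, role="activity"):
    return VoxelVolume(np.asarray(values, float), VOXEL_MM, role)


def _brute_force(img, ref, mask, floor, absolute):
    terms = []
    for idx in np.ndindex(*ref.shape):
        if mask[idx] and ref[idx] >= floor and ref[idx] > 0:
            e = 100.0 * (img[idx] - ref[idx]) / ref[idx]
            terms.append(abs(e) if absolute else e)
    return float(np.mean(terms))


class TestMetrics:
    def test_identical_images_give_zero(self, rng):
        v = rng.random((8, 8)) + 0.5
        m = np.ones((8, 8), bool)
        assert rme(_vol(v), _vol(v), m) == 0.0
        assert rmae(_vol(v), _vol(v), m) == 0.0

    def test_constant_ten_percent_ratio(self, rng):
        ref = rng.random((8, 8)) + 0.5
        m = np.ones((8, 8), bool)
        assert rme(_vol(1.1 * ref), _vol(ref), m) == pytest.approx(10.0)
        assert rmae(_vol(1.1 * ref), _vol(ref), m) == pytest.approx(10.0)

    def test_alternating_errors_cancel_in_rme_not_rmae(self):
        ref = np.ones((4, 4))
        img = ref.copy()
        img[::2] *= 1.1
        img[1::2] *= 0.9
        m = np.ones((4, 4), bool)
        assert rme(_vol(img), _vol(ref), m) == pytest.approx(0.0, abs=1e-10)
        assert rmae(_vol(img), _vol(ref), m) == pytest.approx(10.0)

    def test_two_voxel_hand_computed_case(self):
        ref = np.array([[2.0, 4.0]])
        img = np.array([[2.2, 3.0]])
        m = np.ones((1, 2), bool)
        # voxelwise: +10% and -25% -> mean -7.5%, abs mean 17.5%
        assert rme(_vol(img), _vol(ref), m) == pytest.approx(-7.5)
        assert rmae(_vol(img), _vol(ref), m) == pytest.approx(17.5)

    def test_matches_scalar_brute_force_on_random_volumes(self, rng):
        for _ in range(100):
            ref = rng.random((6, 6)) + 0.1
            img = ref + rng.normal(0, 0.2, ref.shape)
            mask = rng.random(ref.shape) > 0.3
            floor = 0.3
            if not (mask & (ref >= floor)).any():
                continue
            assert abs(rme(_vol(img), _vol(ref), mask, floor)
                       - _brute_force(img, ref, mask, floor, False)) < 1e-10
            assert abs(rmae(_vol(img), _vol(ref), mask, floor)
                       - _brute_force(img, ref, mask, floor, True)) < 1e-10

    @settings(max_examples=30, deadline=None)
    @given(hnp.arrays(np.float64, (5, 5),
                      elements=st.floats(0.1, 10.0)),
           hnp.arrays(np.float64, (5, 5),
                      elements=st.floats(0.1, 10.0)))
    def test_rmae_bounds_abs_rme(self, img, ref):
        m = np.ones((5, 5), bool)
        assert rmae(_vol(img), _vol(ref), m) >= \
            abs(rme(_vol(img), _vol(ref), m)) - 1e-12

    def test_empty_effective_mask_rejected(self):
        with pytest.raises(ValidationError):
            rme(_vol(np.ones((2, 2))), _vol(np.ones((2, 2))),
                np.zeros((2, 2), bool))


class TestSegmentation:
    def test_phantom_labels_recovered_in_interiors(self, table):
        ph = build_phantom(body_phantom_spec((64, 64), seed=3), table)
        masks = segment_tissues(ph.mu(511))
        labels = ph.labels.values
        names = ph.label_names
        assert (masks["fat"].mask == (labels == names.index("fat"))).all()
        # marrow is folded into bone by hole filling
        bone_expected = np.isin(labels, [names.index("bone"),
                                         names.index("bone_marrow")])
        assert (masks["bone"].mask == bone_expected).all()
        water_expected = labels == names.index("soft_tissue")
        assert (masks["water"].mask == water_expected).all()

    def test_cortical_annulus_includes_marrow_via_hole_fill(self):
        mu = np.zeros((32, 32))
        yy, xx = np.meshgrid(np.arange(32) - 15.5, np.arange(32) - 15.5,
                             indexing="ij")
        r = np.hypot(yy, xx)
        mu[r <= 8] = 0.098   # marrow (water range)
        mu[(r > 5) & (r <= 8)] = 0.12  # cortical shell
        vol = VoxelVolume(mu, VOXEL_MM, "mu_map", 511.0)
        masks = segment_tissues(vol)
        assert masks["bone"].mask[r <= 8].all()
        assert not masks["water"].mask[r <= 8].any()

    def test_all_air_gives_empty_masks(self):
        vol = VoxelVolume(np.zeros((8, 8)), VOXEL_MM, "mu_map", 511.0)
        masks = segment_tissues(vol)
        assert all(m.n_voxels == 0 for m in masks.values())

    def test_masks_pairwise_disjoint(self, table):
        ph = build_phantom(body_phantom_spec((64, 64), seed=9), table)
        masks = segment_tissues(ph.mu(511))
        assert not (masks["fat"].mask & masks["water"].mask).any()
        assert not (masks["fat"].mask & masks["bone"].mask).any()
        assert not (masks["water"].mask & masks["bone"].mask).any()


class TestIsocontour:
    def _gaussian_blob(self, shape=(64, 64), center=(31.5, 31.5),
                       sigma=4.0, amp=100.0):
        yy, xx = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]),
                             indexing="ij")
        return amp * np.exp(-(((yy - center[0]) ** 2 + (xx - center[1]) ** 2)
                              / (2 * sigma ** 2)))

    def test_half_max_radius_matches_analytic_level_set(self):
        sigma = 4.0
        pet = _vol(self._gaussian_blob(sigma=sigma))
        mask = isocontour_lesion(pet, (30, 30), 0.5)
        # 50% level set of a Gaussian: radius = sigma * sqrt(2 ln 2)
        expected_r = sigma * np.sqrt(2 * np.log(2))
        area_r = np.sqrt(mask.mask.sum() / np.pi)
        assert area_r == pytest.approx(expected_r, abs=1.0)

    def test_zero_threshold_grabs_whole_connected_region(self):
        img = np.zeros((32, 32))
        img[5:10, 5:10] = 3.0
        mask = isocontour_lesion(_vol(img), (6, 6), 0.0)
        assert mask.mask.sum() == 25

    def test_seed_near_blob_a_excludes_blob_b(self):
        img = (self._gaussian_blob(center=(15, 15), sigma=2.5)
               + self._gaussian_blob(center=(45, 45), sigma=2.5))
        mask = isocontour_lesion(_vol(img), (17, 13), 0.5)
        assert mask.mask[15, 15]
        assert not mask.mask[45, 45]

    def test_zero_activity_seed_rejected(self):
        img = np.zeros((16, 16))
        img[2, 2] = 1.0
        with pytest.raises(ValidationError):
            isocontour_lesion(_vol(img), (10, 10))


class TestSuv:
    def test_uniform_unity(self):
        conc = np.full((4, 4), 2.0e8 / 7.0e4)
        out = suv(_vol(conc), 2.0e8, 7.0e4)
        assert np.allclose(out.values, 1.0)

    def test_doubling_dose_halves_suv(self, rng):
        conc = rng.random((4, 4)) * 1e4
        a = suv(_vol(conc), 1e8, 7e4).values
        b = suv(_vol(conc), 2e8, 7e4).values
        assert np.allclose(b, a / 2)

    def test_two_region_voi_mean_hand_computed(self):
        conc = np.zeros((4, 4))
        conc[:2] = 6000.0
        conc[2:] = 2000.0
        out = suv(_vol(conc), 2.0e8, 8.0e4)  # dose/weight = 2500 Bq/g
        voi = np.ones((4, 4), bool)
        assert out.values[voi].mean() == pytest.approx(4000.0 / 2500.0)

    def test_nonpositive_dose_rejected(self):
        with pytest.raises(ValidationError):
            suv(_vol(np.ones((2, 2))), 0.0, 1.0)


class TestReport:
    def test_reference_vs_itself_is_all_zero(self, table):
        ph = build_phantom(body_phantom_spec((64, 64), seed=3), table)
        masks = segment_tissues(ph.mu(511))
        rep = build_report({"reference": ph.mu(511),
                            "copy": ph.mu(511)}, "reference", masks)
        assert (rep.table["rme_pct"] == 0).all()
        assert (rep.table["rmae_pct"] == 0).all()

    def test_rows_match_direct_metric_calls(self, table, rng):
        ph = build_phantom(body_phantom_spec((64, 64), seed=3), table)
        truth = ph.mu(511)
        noisy = truth.with_values(
            np.clip(truth.values * (1 + rng.normal(0, 0.05, truth.shape)),
                    0, None))
        masks = segment_tissues(truth)
        rep = build_report({"reference": truth, "noisy": noisy}, "reference",
                           masks, ref_floor_frac=0.5)
        from petmu.evaluate import mu_ref_floor

        for _, row in rep.table.iterrows():
            voi = masks[row["voi"]]
            floor = mu_ref_floor(truth, voi.mask, 0.5)
            assert row["rme_pct"] == pytest.approx(
                rme(noisy, truth, voi, floor))
            assert row["rmae_pct"] == pytest.approx(
                rmae(noisy, truth, voi, floor))
            assert row["rmae_pct"] >= abs(row["rme_pct"]) - 1e-12

    def test_missing_reference_rejected(self):
        with pytest.raises(ValidationError):
            build_report({"a": _vol(np.ones((2, 2)))}, "reference", {})
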