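"""MLTR, TOF-OSEM, MLACF and factor-to-mu extraction."""

import numpy as np
import pytest
from scipy.ndimage import binary_erosion
from scipy.optimize import minimize_scalar

from petmu.core import Sinogram, ValidationError, VoxelVolume
from petmu.projector import attenuation_factors, project_array
from petmu.recon import (AcfToMuConfig, MlacfConfig, MltrConfig, OsemConfig,
                         acf_to_mu, emission_loglik, mlacf,
                         mlacf_factor_step, mltr, osem_tof)
from petmu.simulate import simulate_emission, simulate_transmission

from conftest import VOXEL_MM

W307 = (275.0, 355.0)


def _interior(phantom, iters=2):
    return binary_erosion(phantom.labels.values > 0, iterations=iters)


def _rmae(a, b, mask):
    return float(np.mean(np.abs(a[mask] - b[mask]) / b[mask]))


class TestMltr:
    def test_noiseless_two_compartment_recovery(self, scanner64, disk_phantom):
        counts, blank = simulate_transmission(disk_phantom.mu(307), scanner64,
                                              W307, 300.0, noiseless=True)
        mu = mltr(counts, blank, scanner64, MltrConfig(iterations=40),
                  grid_shape=(64, 64), voxel_size_mm=VOXEL_MM)
        mask = _interior(disk_phantom)
        assert _rmae(mu.values, disk_phantom.mu(307).values, mask) < 0.02

    def test_no_object_fixed_point_is_zero(self, scanner64):
        zero_mu = VoxelVolume(np.zeros((64, 64)), VOXEL_MM, "mu_map", 307.0)
        counts, blank = simulate_transmission(zero_mu, scanner64, W307, 300.0,
                                              noiseless=True)
        mu = mltr(counts, blank, scanner64, MltrConfig(),
                  grid_shape=(64, 64), voxel_size_mm=VOXEL_MM)
        assert np.abs(mu.values).max() < 1e-3

    def test_loglik_nondecreasing_one_subset(self, scanner64, disk_phantom):
        counts, blank = simulate_transmission(disk_phantom.mu(307), scanner64,
                                              W307, 300.0, noiseless=True)
        _, trace = mltr(counts, blank, scanner64,
                        MltrConfig(iterations=15, subsets=1),
                        grid_shape=(64, 64), voxel_size_mm=VOXEL_MM,
                        return_loglik=True)
        assert all(b >= a - 1e-9 * abs(a) for a, b in zip(trace, trace[1:]))

    def test_nonnegativity_preserved(self, scanner64, disk_phantom):
        counts, blank = simulate_transmission(disk_phantom.mu(307), scanner64,
                                              W307, 300.0, seed=4)
        mu = mltr(counts, blank, scanner64, MltrConfig(),
                  grid_shape=(64, 64), voxel_size_mm=VOXEL_MM)
        assert (mu.values >= 0).all()

    def test_all_zero_blank_rejected(self, scanner64):
        z = Sinogram(np.zeros((scanner64.n_angles, scanner64.n_radial)),
                     "counts", scanner=scanner64)
        with pytest.raises(ValidationError):
            mltr(z, z, scanner64, MltrConfig(), grid_shape=(64, 64))

    def test_nan_counts_rejected(self, scanner64):
        vals = np.ones((scanner64.n_angles, scanner64.n_radial))
        blank = Sinogram(vals, "counts", scanner=scanner64)
        bad = vals.copy()
        bad[0, 0] = np.nan
        counts = Sinogram(bad, "counts", scanner=scanner64)
        with pytest.raises(ValidationError):
            mltr(counts, blank, scanner64, MltrConfig(), grid_shape=(64, 64))


class TestOsemTof:
    def test_point_source_maximum_recovered(self, scanner64, kernel64):
        img = np.zeros((64, 64))
        img[40, 25] = 1000.0
        act = VoxelVolume(img, VOXEL_MM, "activity")
        mu = VoxelVolume(np.zeros((64, 64)), VOXEL_MM, "mu_map", 511.0)
        em = simulate_emission(act, mu, scanner64, kernel64, 600.0,
                               noiseless=True)
        rec = osem_tof(em.counts, em.acf, None, scanner64, kernel64,
                       OsemConfig(iterations=6, postfilter_fwhm_mm=0.0),
                       grid_shape=(64, 64), voxel_size_mm=VOXEL_MM)
        assert np.unravel_index(np.argmax(rec.values), (64, 64)) == (40, 25)

    def test_zero_counts_give_zero_image(self, scanner64, kernel64):
        shape = (scanner64.n_angles, scanner64.n_radial, kernel64.n_bins)
        counts = Sinogram(np.zeros(shape), "counts", has_tof=True)
        acf = Sinogram(np.ones(shape[:2]), "attenuation_factor")
        rec = osem_tof(counts, acf, None, scanner64, kernel64,
                       OsemConfig(iterations=2, postfilter_fwhm_mm=0.0),
                       grid_shape=(64, 64), voxel_size_mm=VOXEL_MM)
        assert not rec.values.any()

    def test_uniform_disk_voi_mean_within_3pct(self, scanner64, kernel64,
                                               disk_phantom):
        em = simulate_emission(disk_phantom.activity, disk_phantom.mu(511),
                               scanner64, kernel64, 600.0, noiseless=True)
        rec = osem_tof(em.counts, em.acf, em.additive, scanner64, kernel64,
                       OsemConfig(iterations=10, postfilter_fwhm_mm=0.0),
                       grid_shape=(64, 64), voxel_size_mm=VOXEL_MM)
        scale = 600.0 * 2e-4  # duration * sensitivity
        names = disk_phantom.label_names
        voi = binary_erosion(
            disk_phantom.labels.values == names.index("soft_tissue"),
            iterations=2)
        truth = disk_phantom.activity.values[voi].mean()
        got = rec.values[voi].mean() / scale
        assert got == pytest.approx(truth, rel=0.03)

    def test_one_subset_equals_explicit_mlem(self, scanner64, kernel64,
                                             disk_phantom):
        """OSEM with one subset must reproduce a hand-rolled full-angle MLEM
        loop composed directly from the projector primitives."""
        from petmu.projector import backproject_array

        em = simulate_emission(disk_phantom.activity, disk_phantom.mu(511),
                               scanner64, kernel64, 600.0, seed=3)
        got = osem_tof(em.counts, em.acf, em.additive, scanner64, kernel64,
                       OsemConfig(iterations=3, subsets=1,
                                  postfilter_fwhm_mm=0.0),
                       grid_shape=(64, 64), voxel_size_mm=VOXEL_MM)
        y = em.counts.values
        a = em.acf.values
        add = em.additive.values
        lam = np.ones((64, 64))
        sens = backproject_array(a, (64, 64), VOXEL_MM, scanner64)
        for _ in range(3):
            fp = project_array(lam, VOXEL_MM, scanner64, kernel=kernel64)
            ybar = a[..., None] * fp + add
            ratio = np.where(ybar > 1e-12, y / np.clip(ybar, 1e-12, None), 0.0)
            bp = backproject_array(a[..., None] * ratio, (64, 64), VOXEL_MM,
                                   scanner64, kernel=kernel64)
            lam = np.where(sens > 1e-12,
                           lam * bp / np.clip(sens, 1e-12, None), 0.0)
        assert np.allclose(got.values, lam, rtol=1e-10, atol=1e-12)

    def test_negative_counts_rejected(self, scanner64, kernel64):
        shape = (scanner64.n_angles, scanner64.n_radial, kernel64.n_bins)
        vals = np.zeros(shape)
        vals[0, 0, 0] = -1.0
        counts = Sinogram(np.abs(vals), "counts", has_tof=True)
        counts.values = vals  # bypass constructor check to hit op validation
        acf = Sinogram(np.ones(shape[:2]), "attenuation_factor")
        with pytest.raises(ValidationError):
            osem_tof(counts, acf, None, scanner64, kernel64, OsemConfig(),
                     grid_shape=(64, 64))


@pytest.fixture(scope="module")
def noiseless_result(scanner64, kernel64, body_phantom):
    em = simulate_emission(body_phantom.activity, body_phantom.mu(511),
                           scanner64, kernel64, 600.0, noiseless=True)
    res = mlacf(em.counts, em.additive, scanner64, kernel64,
                body_phantom.mu(511), MlacfConfig(), track_loglik=True)
    return em, res


class TestMlacf:
    def test_activity_voi_means_within_5pct(self, noiseless_result,
                                            body_phantom):
        em, res = noiseless_result
        scale = 600.0 * 2e-4
        labels = body_phantom.labels.values
        names = body_phantom.label_names
        for tissue in ("soft_tissue", "fat", "bone_marrow"):
            voi = binary_erosion(labels == names.index(tissue), iterations=1)
            if not voi.any():
                continue
            truth = body_phantom.activity.values[voi].mean()
            got = res.activity.values[voi].mean() / scale
            assert got == pytest.approx(truth, rel=0.05), tissue

    def test_factor_estimates_close_to_truth_where_signal(
            self, noiseless_result, body_phantom, scanner64):
        em, res = noiseless_result
        p_lam = project_array(body_phantom.activity.values, VOXEL_MM,
                              scanner64)
        mask = p_lam > 0
        rel = np.abs(res.acf.values[mask] - em.acf.values[mask]) \
            / em.acf.values[mask]
        assert rel.mean() < 0.02

    def test_loglik_trace_nondecreasing(self, noiseless_result):
        _, res = noiseless_result
        t = res.loglik_trace
        assert all(b >= a - 1e-9 * abs(a) for a, b in zip(t, t[1:]))

    def test_scale_ambiguity_of_factored_mean(self, noiseless_result,
                                              scanner64, kernel64):
        em, res = noiseless_result
        lam = res.activity.values
        a = res.acf.values
        args = (em.additive.values, em.counts.values, scanner64, kernel64,
                (VOXEL_MM, VOXEL_MM))
        ll1 = emission_loglik(lam, a, *args)
        c = 1.37
        ll2 = emission_loglik(lam * c, a / c, *args)
        assert abs(ll1 - ll2) / abs(ll1) < 1e-8

    def test_factor_step_matches_scalar_brute_force(self, rng):
        """The closed-form per-LOR factor maximises the Poisson likelihood:
        check against a numeric 1-D maximiser on random LORs."""
        n = 50
        p_lam = rng.uniform(5.0, 50.0, n)
        add = rng.uniform(0.0, 5.0, n)
        a_true = rng.uniform(0.05, 1.0, n)
        y = a_true * p_lam + add  # noiseless counts
        a_hat = mlacf_factor_step(y, add, p_lam, np.ones(n), 1e-3, 1.0,
                                  min_plam_frac=0.0)
        for i in range(n):
            def nll(a):
                mean = max(a * p_lam[i] + add[i], 1e-12)
                return -(y[i] * np.log(mean) - mean)

            best = minimize_scalar(nll, bounds=(1e-3, 1.0), method="bounded",
                                   options={"xatol": 1e-12})
            assert abs(a_hat[i] - best.x) < 1e-6

    def test_all_zero_counts_rejected(self, scanner64, kernel64,
                                      body_phantom):
        shape = (scanner64.n_angles, scanner64.n_radial, kernel64.n_bins)
        counts = Sinogram(np.zeros(shape), "counts", has_tof=True)
        with pytest.raises(ValidationError):
            mlacf(counts, None, scanner64, kernel64, body_phantom.mu(511))


class TestAcfToMu:
    def test_true_factors_recovered_in_interior(self, scanner64,
                                                body_phantom):
        acf = attenuation_factors(body_phantom.mu(511), scanner64)
        mu = acf_to_mu(acf, scanner64, init=body_phantom.mu(511),
                       cfg=AcfToMuConfig())
        mask = _interior(body_phantom)
        assert _rmae(mu.values, body_phantom.mu(511).values, mask) < 0.02

    def test_all_ones_factors_give_zero_mu(self, scanner64):
        ones = Sinogram(np.ones((scanner64.n_angles, scanner64.n_radial)),
                        "attenuation_factor", scanner=scanner64)
        init = VoxelVolume(np.full((64, 64), 0.05), VOXEL_MM, "mu_map", 511.0)
        mu = acf_to_mu(ones, scanner64, init=init)
        assert np.abs(mu.values).max() < 1e-4

    def test_init_independence_on_noiseless_data(self, scanner64,
                                                 body_phantom):
        acf = attenuation_factors(body_phantom.mu(511), scanner64)
        zero_init = VoxelVolume(np.zeros((64, 64)), VOXEL_MM, "mu_map", 511.0)
        mu_a = acf_to_mu(acf, scanner64, init=body_phantom.mu(511))
        mu_b = acf_to_mu(acf, scanner64, init=zero_init)
        mask = _interior(body_phantom)
        assert _rmae(mu_a.values, np.maximum(mu_b.values, 1e-9), mask) < 0.005
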