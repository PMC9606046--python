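"""Iterative reconstruction: MLTR, TOF-OSEM, and MLACF joint estimation.

Models
------
Transmission (per LOR i): ``ybar_i = b_i exp(-(P mu)_i)`` with Poisson
counts; MLTR performs ordered-subsets maximum-likelihood ascent with the
separable-paraboloid (convex) update

    mu <- mu + P'(ybar - y) / P'[(P 1) ybar],   clamped >= 0,

which is monotone in the one-subset limit.

Emission (per LOR i, TOF bin t): ``ybar_it = a_i (P lambda)_it + s_it`` with
known additive ``s`` (scatter + randoms); TOF-OSEM applies the multiplicative
update ``lambda <- lambda * P'[a y / ybar] / P'[a]``, optionally with an
image-space Gaussian PSF inside the system model and a Gaussian post-filter.

MLACF alternates, per global iteration: (1) one OSEM pass for the activity
with the current factors; (2) the closed-form per-LOR maximum-likelihood
factor ``a_i = (sum_t y_it - sum_t s_it) / sum_t (P lambda)_it`` clipped to
[floor, 1]; (3) scale anchoring — the factored mean ``a (P lambda)`` is
invariant under ``(lambda c, a / c)``, so one global scalar is applied to all
factors (its inverse to the activity), chosen to match the mean log-factor
predicted by the transmission-derived initial mu-map over a body mask. The
final mu-map is extracted from the factors by penalised weighted
least-squares on the pseudo line integrals ``-ln a``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Optional, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.sparse.linalg import LinearOperator, cg

from .core import Sinogram, ValidationError, VoxelVolume
from .projector import (attenuation_factors, backproject_array, project_array)
from .scanner import FWHM_TO_SIGMA, ScannerModel, TofKernel

_EPS = 1e-12


def _subset_angles(n_angles: int, n_subsets: int) -> List[np.ndarray]:
    """Interleaved angle subsets (standard OSEM ordering)."""
    if n_subsets < 1:
        raise ValidationError("subsets must be >= 1")
    n_subsets = min(n_subsets, n_angles)
    return [np.arange(s, n_angles, n_subsets) for s in range(n_subsets)]


def _smooth(values: np.ndarray, fwhm_mm: float, voxel_size_mm) -> np.ndarray:
    if fwhm_mm <= 0:
        return values
    sigmas = [fwhm_mm * FWHM_TO_SIGMA / v for v in voxel_size_mm]
    return gaussian_filter(values, sigmas, mode="nearest")


# ------------------------------------------------------------------- MLTR

@dataclass(frozen=True)
class MltrConfig:
    iterations: int = 8
    subsets: int = 3
    nonneg: bool = True
    stop_tol: float = 0.0  # relative mu change; 0 disables early stopping

    def __post_init__(self):
        if self.iterations < 1:
            raise ValidationError("iterations must be >= 1")


def transmission_loglik(mu_values: np.ndarray, counts: np.ndarray,
                        blank: np.ndarray, scanner: ScannerModel,
                        voxel_size_mm) -> float:
    """Poisson log-likelihood (up to the y! constant) of a mu-map."""
    line = project_array(mu_values, voxel_size_mm, scanner)
    ybar = np.clip(blank * np.exp(-line), _EPS, None)
    return float(np.sum(counts * np.log(ybar) - ybar))


def mltr(counts: Sinogram, blank: Sinogram, scanner: ScannerModel,
         cfg: MltrConfig = MltrConfig(), init: Optional[VoxelVolume] = None,
         grid_shape: Optional[Tuple[int, ...]] = None,
         voxel_size_mm: float = 1.65, return_loglik: bool = False):
    """Ordered-subsets MLTR for the Poisson transmission model.

    Returns the reconstructed mu-map tagged with the counts' energy; with
    ``return_loglik=True`` also a per-full-iteration log-likelihood trace.
    """
    y = np.asarray(counts.values, dtype=float)
    b = np.asarray(blank.values, dtype=float)
    if y.shape != b.shape:
        raise ValidationError("counts and blank must have the same shape")
    if np.any(~np.isfinite(y)) or np.any(~np.isfinite(b)):
        raise ValidationError("NaN/inf in MLTR inputs")
    if not np.any(b > 0):
        raise ValidationError("blank sinogram is all zero")
    if np.any((y > 0) & (b <= 0)):
        raise ValidationError("counts observed where blank is zero")

    if init is not None:
        mu = np.asarray(init.values, dtype=float).copy()
        grid_shape = mu.shape
        voxel_size_mm = init.voxel_size_mm
    else:
        if grid_shape is None:
            n = scanner.n_radial
            grid_shape = (n, n) if y.ndim == 2 else (y.shape[2], n, n)
        mu = np.zeros(grid_shape)
    vsz = voxel_size_mm

    subsets = _subset_angles(scanner.n_angles, cfg.subsets)
    ones = np.ones(grid_shape)
    trace = []
    for it in range(cfg.iterations):
        mu_prev = mu.copy()
        for sub in subsets:
            line = project_array(mu, vsz, scanner, angle_indices=sub)
            ybar = b[sub] * np.exp(-line)
            grad = backproject_array(ybar - y[sub], grid_shape, vsz, scanner,
                                     angle_indices=sub)
            p1 = project_array(ones, vsz, scanner, angle_indices=sub)
            curv = backproject_array(p1 * ybar, grid_shape, vsz, scanner,
                                     angle_indices=sub)
            step = np.where(curv > _EPS, grad / np.clip(curv, _EPS, None), 0.0)
            mu = mu + step
            if cfg.nonneg:
                mu = np.clip(mu, 0.0, None)
        if return_loglik:
            trace.append(transmission_loglik(mu, y, b, scanner, _vsz(vsz, grid_shape)))
        if cfg.stop_tol > 0:
            denom = np.abs(mu_prev).max() + _EPS
            if np.abs(mu - mu_prev).max() / denom < cfg.stop_tol:
                break
    vol = VoxelVolume(np.clip(mu, 0.0, None), _vsz(vsz, grid_shape), "mu_map",
                      counts.energy_kev if counts.energy_kev else 511.0)
    return (vol, trace) if return_loglik else vol


def _vsz(voxel_size_mm, grid_shape):
    if np.isscalar(voxel_size_mm):
        return (float(voxel_size_mm),) * len(grid_shape)
    return tuple(voxel_size_mm)


# --------------------------------------------------------------- TOF-OSEM

@dataclass(frozen=True)
class OsemConfig:
    iterations: int = 4
    subsets: int = 5
    psf_fwhm_mm: float = 0.0        # image-space PSF inside the system model
    postfilter_fwhm_mm: float = 2.0

    def __post_init__(self):
        if self.iterations < 1:
            raise ValidationError("iterations must be >= 1")


def emission_loglik(lam_values: np.ndarray, acf: np.ndarray,
                    additive: np.ndarray, counts: np.ndarray,
                    scanner: ScannerModel, kernel: TofKernel,
                    voxel_size_mm) -> float:
    """Poisson log-likelihood of the factored emission mean model."""
    p_lam = project_array(lam_values, voxel_size_mm, scanner, kernel=kernel)
    ybar = np.clip(acf[..., None] * p_lam + additive, _EPS, None)
    return float(np.sum(counts * np.log(ybar) - ybar))


def osem_tof(counts: Sinogram, acf: Sinogram, additive: Optional[Sinogram],
             scanner: ScannerModel, kernel: TofKernel,
             cfg: OsemConfig = OsemConfig(), init: Optional[VoxelVolume] = None,
             grid_shape: Optional[Tuple[int, ...]] = None,
             voxel_size_mm: float = 1.65) -> VoxelVolume:
    """TOF-OSEM emission reconstruction with known additive background."""
    y = np.asarray(counts.values, dtype=float)
    a = np.asarray(acf.values, dtype=float)
    if np.any(y < 0):
        raise ValidationError("negative counts")
    if np.any(a <= 0) or np.any(a > 1 + 1e-9):
        raise ValidationError("attenuation factors must lie in (0, 1]")
    add = (np.zeros_like(y) if additive is None
           else np.asarray(additive.values, dtype=float))
    if add.shape != y.shape or a.shape != y.shape[:-1]:
        raise ValidationError("sinogram shape mismatch")
    if np.any(add < 0):
        raise ValidationError("additive term must be non-negative")

    if init is not None:
        lam = np.asarray(init.values, dtype=float).copy()
        grid_shape = lam.shape
        voxel_size_mm = init.voxel_size_mm
    else:
        if grid_shape is None:
            n = scanner.n_radial
            grid_shape = (n, n) if y.ndim == 3 else (y.shape[2], n, n)
        lam = np.ones(grid_shape)
    vsz = _vsz(voxel_size_mm, grid_shape)
    psf = cfg.psf_fwhm_mm

    subsets = _subset_angles(scanner.n_angles, cfg.subsets)
    sens = []
    for sub in subsets:
        s = backproject_array(a[sub], grid_shape, vsz, scanner,
                              angle_indices=sub)
        if psf > 0:
            s = _smooth(s, psf, vsz)
        sens.append(s)

    for it in range(cfg.iterations):
        for sub, s in zip(subsets, sens):
            img = _smooth(lam, psf, vsz) if psf > 0 else lam
            fp = project_array(img, vsz, scanner, angle_indices=sub,
                               kernel=kernel)
            ybar = a[sub][..., None] * fp + add[sub]
            ratio = np.where(ybar > _EPS, y[sub] / np.clip(ybar, _EPS, None), 0.0)
            bp = backproject_array(a[sub][..., None] * ratio, grid_shape, vsz,
                                   scanner, angle_indices=sub, kernel=kernel)
            if psf > 0:
                bp = _smooth(bp, psf, vsz)
            lam = np.where(s > _EPS, lam * bp / np.clip(s, _EPS, None), 0.0)
            lam = np.clip(lam, 0.0, None)

    if cfg.postfilter_fwhm_mm > 0:
        lam = _smooth(lam, cfg.postfilter_fwhm_mm, vsz)
    return VoxelVolume(lam, vsz, "activity")


# ------------------------------------------------------------------ MLACF

@dataclass(frozen=True)
class AcfToMuConfig:
    beta: float = 1e-3          # quadratic smoothness weight
    iterations: int = 100       # conjugate-gradient iterations
    acf_floor: float = 1e-3


@dataclass(frozen=True)
class MlacfConfig:
    global_iterations: int = 20
    inner: OsemConfig = OsemConfig(iterations=1, subsets=5,
                                   postfilter_fwhm_mm=0.0)
    acf_floor: float = 1e-3
    acf_ceiling: float = 1.0
    anchor_frac: float = 0.98   # body mask rule: a_init < frac * max(a_init)
    min_plam_frac: float = 1e-3  # LORs below this keep the init factor
    warmup_passes: int = 10     # OSEM passes with init factors before alternating
    # factor estimates from joint reconstruction are Poisson-noisy per LOR,
    # so the default extraction smooths much harder than the noiseless default
    extract: AcfToMuConfig = AcfToMuConfig(beta=0.1)

    def __post_init__(self):
        if self.global_iterations < 1:
            raise ValidationError("global_iterations must be >= 1")
        if not 0 < self.acf_floor <= self.acf_ceiling <= 1:
            raise ValidationError("need 0 < floor <= ceiling <= 1")


@dataclass
class MlacfResult:
    activity: VoxelVolume
    acf: Sinogram
    mu_map: VoxelVolume
    loglik_trace: List[float]


def mlacf_factor_step(y_sum: np.ndarray, add_sum: np.ndarray,
                      p_lam_sum: np.ndarray, a_init: np.ndarray,
                      floor: float, ceiling: float = 1.0,
                      min_plam_frac: float = 1e-3) -> np.ndarray:
    """Closed-form per-LOR ML factor update (TOF-summed statistics).

    LORs with (near-)zero unattenuated projection keep their
    initialisation-derived factor: the likelihood carries essentially no
    information about them (the ML estimate's variance scales like
    ``1 / (P lambda)``), so the transmission-derived prior factor is
    retained below ``min_plam_frac`` of the maximum projection.
    """
    num = y_sum - add_sum
    thresh = max(_EPS, min_plam_frac * float(p_lam_sum.max()))
    with np.errstate(divide="ignore", invalid="ignore"):
        a_hat = np.where(p_lam_sum > thresh,
                         num / np.clip(p_lam_sum, _EPS, None), a_init)
    return np.clip(a_hat, floor, ceiling)


def mlacf(counts: Sinogram, additive: Optional[Sinogram],
          scanner: ScannerModel, kernel: TofKernel, init_mu: VoxelVolume,
          cfg: MlacfConfig = MlacfConfig(),
          track_loglik: bool = True) -> MlacfResult:
    """Joint activity / attenuation-factor estimation seeded by a mu-map."""
    y = np.asarray(counts.values, dtype=float)
    if not np.any(y > 0):
        raise ValidationError("emission counts are all zero")
    if np.any(init_mu.values < 0):
        raise ValidationError("init_mu must be non-negative")
    if init_mu.energy_kev is None or abs(init_mu.energy_kev - 511.0) > 1e-6:
        raise ValidationError("init_mu must be a 511 keV mu-map")
    add = (np.zeros_like(y) if additive is None
           else np.asarray(additive.values, dtype=float))
    grid_shape = init_mu.shape
    vsz = init_mu.voxel_size_mm

    a_init = attenuation_factors(init_mu, scanner).values
    a = np.clip(a_init, cfg.acf_floor, cfg.acf_ceiling)
    anchor_target = None
    lam_vol = VoxelVolume(np.ones(grid_shape), vsz, "activity")

    y_sum = y.sum(axis=-1)
    add_sum = add.sum(axis=-1)
    trace = []
    if cfg.warmup_passes > 0:
        # settle the activity against the transmission-derived factors before
        # the first factor update; a factor step against a barely-converged
        # activity corrupts low-signal LORs and feeds back into the activity
        warm = replace(cfg.inner, iterations=cfg.warmup_passes)
        lam_vol = osem_tof(counts,
                           Sinogram(a, "attenuation_factor", scanner=scanner),
                           None if additive is None else additive,
                           scanner, kernel, warm, init=lam_vol)
    for it in range(cfg.global_iterations):
        # (1) activity step: one OSEM pass with current factors
        acf_sino = Sinogram(a, "attenuation_factor", scanner=scanner)
        lam_vol = osem_tof(counts, acf_sino,
                           None if additive is None else additive,
                           scanner, kernel, cfg.inner, init=lam_vol)
        # (2) closed-form factor step
        p_lam_sum = project_array(lam_vol.values, vsz, scanner)
        a = mlacf_factor_step(y_sum, add_sum, p_lam_sum,
                              np.clip(a_init, cfg.acf_floor, cfg.acf_ceiling),
                              cfg.acf_floor, cfg.acf_ceiling,
                              cfg.min_plam_frac)
        # (3) anchoring: one global scalar against the transmission prior
        mask = (a_init < cfg.anchor_frac * a_init.max()) & \
            (p_lam_sum > cfg.min_plam_frac * p_lam_sum.max())
        if mask.any():
            log_c = np.mean(np.log(np.clip(a_init[mask], cfg.acf_floor, 1.0))
                            - np.log(a[mask]))
            c = float(np.exp(log_c))
            a = np.clip(a * c, cfg.acf_floor, cfg.acf_ceiling)
            lam_vol = lam_vol.with_values(lam_vol.values / c)
        if track_loglik:
            p_lam = project_array(lam_vol.values, vsz, scanner, kernel=kernel)
            ybar = np.clip(a[..., None] * p_lam + add, _EPS, None)
            trace.append(float(np.sum(y * np.log(ybar) - ybar)))

    acf_sino = Sinogram(a, "attenuation_factor", scanner=scanner,
                        energy_kev=511.0)
    # trues-based confidence: var(-ln a_hat) ~ 1/trues for Poisson data
    weights = np.clip(y_sum - add_sum, 0.0, None)
    mu = acf_to_mu(acf_sino, scanner, init=init_mu, cfg=cfg.extract,
                   weights=weights)
    return MlacfResult(activity=lam_vol, acf=acf_sino, mu_map=mu,
                       loglik_trace=trace)


# -------------------------------------------------------------- ACF -> mu

def acf_to_mu(acf: Sinogram, scanner: ScannerModel, init: VoxelVolume,
              cfg: AcfToMuConfig = AcfToMuConfig(),
              weights: Optional[np.ndarray] = None) -> VoxelVolume:
    """Reconstruct a mu-map from attenuation factors.

    Solves the penalised weighted least-squares problem
    ``min_mu ||W^1/2 (P mu - p)||^2 + beta ||grad mu||^2`` with
    ``p = -ln(a)`` by conjugate gradients, started from ``init``, and clamps
    the result at zero. ``weights`` default to uniform; pass counts-based
    confidences for noisy factors. Factors at/below zero are clamped to the
    configured floor (counted as a warning in the returned volume's metadata
    is out of scope; the clamp count is logged via warnings).
    """
    a = np.asarray(acf.values, dtype=float)
    n_clamped = int(np.sum(a < cfg.acf_floor))
    if n_clamped:
        import warnings

        warnings.warn(f"acf_to_mu: {n_clamped} factors clamped at floor "
                      f"{cfg.acf_floor}", stacklevel=2)
    a = np.clip(a, cfg.acf_floor, 1.0)
    p = -np.log(a)
    grid_shape = init.shape
    vsz = init.voxel_size_mm
    w = np.ones_like(p) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != p.shape or np.any(w < 0):
        raise ValidationError("weights must be a non-negative sinogram")
    wmax = w.max()
    if wmax <= 0:
        raise ValidationError("all-zero weights")
    w = w / wmax

    n = int(np.prod(grid_shape))

    def laplacian(x):
        # negative Laplacian with reflective boundaries (symmetric PSD)
        from scipy.ndimage import laplace

        return -laplace(x, mode="nearest")

    def matvec(x):
        xv = x.reshape(grid_shape)
        px = project_array(xv, vsz, scanner)
        bp = backproject_array(w * px, grid_shape, vsz, scanner)
        return (bp + cfg.beta * laplacian(xv)).ravel()

    rhs = backproject_array(w * p, grid_shape, vsz, scanner).ravel()
    A = LinearOperator((n, n), matvec=matvec)
    x0 = np.asarray(init.values, dtype=float).ravel()
    sol, _ = cg(A, rhs, x0=x0, maxiter=cfg.iterations, rtol=1e-8, atol=0.0)
    return VoxelVolume(np.clip(sol.reshape(grid_shape), 0.0, None), vsz,
                       "mu_map", 511.0)
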