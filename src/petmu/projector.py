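"""Parallel-beam forward/back-projection, with and without time-of-flight.

A ray-driven projector with bilinear interpolation: each line of response is
sampled at fixed steps, the volume is gathered bilinearly at the sample
points, and samples are summed times the step length (in cm). The gather is
materialised once per (scanner geometry, grid, angle subset) as a sparse
matrix ``G``; the adjoint applies ``G^T`` through exactly the same weights,
so ``<Px, y> == <x, P'y>`` holds to floating-point rounding by construction.

3-D volumes ``(nz, ny, nx)`` are projected slice-by-slice (the parallel-beam
geometry is separable in z); the sinogram gains a trailing z axis before the
optional TOF axis.

TOF projection distributes each sample over TOF bins with a Gaussian kernel
centred at the sample's signed offset along the ray; because kernel rows are
renormalised, summing a TOF sinogram over bins reproduces the non-TOF
projection exactly.
"""

from __future__ import annotations

from collections import OrderedDict
from typing import Optional, Tuple

import numpy as np
import scipy.sparse as sp

from .core import Sinogram, ValidationError, VoxelVolume
from .scanner import ScannerModel, TofKernel

MM_PER_CM = 10.0

# geometry cache: small FIFO, entries can be large for big grids
_CACHE: "OrderedDict[tuple, tuple]" = OrderedDict()
_CACHE_MAX = 6


def _grid_2d(volume_shape, voxel_size_mm):
    ny, nx = volume_shape[-2:]
    vy, vx = voxel_size_mm[-2:]
    return ny, nx, vy, vx


def _ray_samples(scanner: ScannerModel, volume_shape, voxel_size_mm):
    """Radial offsets, step offsets and step length (all mm) for one view."""
    ny, nx, vy, vx = _grid_2d(volume_shape, voxel_size_mm)
    du = scanner.radial_spacing_mm
    us = (np.arange(scanner.n_radial) - (scanner.n_radial - 1) / 2.0) * du
    dt = min(vy, vx)
    half_diag = 0.5 * np.hypot(ny * vy, nx * vx)
    n_steps = int(np.ceil(2 * half_diag / dt)) + 1
    ts = (np.arange(n_steps) - (n_steps - 1) / 2.0) * dt
    return us, ts, dt


def _bilinear_terms(theta, us, ts, volume_shape, voxel_size_mm):
    """Corner flat-indices and weights, shapes ``(4, R*S)``.

    Out-of-grid corners get zero weight and a clamped index, which keeps
    gather and scatter exact transposes of each other.
    """
    ny, nx, vy, vx = _grid_2d(volume_shape, voxel_size_mm)
    ct, st = np.cos(theta), np.sin(theta)
    # lateral axis (-sin, cos), ray direction (cos, sin) in (x, y)
    x = us[:, None] * (-st) + ts[None, :] * ct
    y = us[:, None] * ct + ts[None, :] * st
    col = x / vx + (nx - 1) / 2.0
    row = y / vy + (ny - 1) / 2.0
    r0 = np.floor(row).astype(np.int64)
    c0 = np.floor(col).astype(np.int64)
    fr = row - r0
    fc = col - c0
    idx4 = np.empty((4,) + row.shape, dtype=np.int64)
    w4 = np.empty((4,) + row.shape)
    for k, (dr, dc) in enumerate(((0, 0), (0, 1), (1, 0), (1, 1))):
        rr = r0 + dr
        cc = c0 + dc
        w = (fr if dr else (1.0 - fr)) * (fc if dc else (1.0 - fc))
        inside = (rr >= 0) & (rr < ny) & (cc >= 0) & (cc < nx)
        w4[k] = np.where(inside, w, 0.0)
        idx4[k] = np.clip(rr, 0, ny - 1) * nx + np.clip(cc, 0, nx - 1)
    flat = row.shape[0] * row.shape[1]
    return idx4.reshape(4, flat), w4.reshape(4, flat)


def _vsz_shape(shape, voxel_size_mm):
    if np.isscalar(voxel_size_mm):
        return (float(voxel_size_mm),) * len(shape)
    voxel_size_mm = tuple(float(v) for v in voxel_size_mm)
    if len(voxel_size_mm) != len(shape):
        raise ValidationError("voxel size dimensionality mismatch")
    return voxel_size_mm


def _angle_tuple(scanner: ScannerModel, angle_indices) -> tuple:
    if angle_indices is None:
        return tuple(range(scanner.n_angles))
    return tuple(int(a) for a in angle_indices)


def _geometry(scanner: ScannerModel, grid_shape, voxel_size_mm, angle_indices):
    """Cached (G, G^T, us, ts, dt) for one geometry and angle subset."""
    shape2 = tuple(grid_shape[-2:])
    vsz = _vsz_shape(grid_shape, voxel_size_mm)[-2:]
    angles = _angle_tuple(scanner, angle_indices)
    key = (scanner, shape2, vsz, angles)
    hit = _CACHE.get(key)
    if hit is not None:
        _CACHE.move_to_end(key)
        return hit
    ny, nx = shape2
    us, ts, dt = _ray_samples(scanner, shape2, vsz)
    R, S = len(us), len(ts)
    all_angles = scanner.angles_rad
    rows_per_angle = R * S
    n_rows = len(angles) * rows_per_angle
    # build directly in CSR layout: every row (= one ray sample) has exactly
    # its 4 bilinear corners, so indptr is uniform and no COO sort is needed
    data = np.empty((len(angles), rows_per_angle, 4))
    cols = np.empty((len(angles), rows_per_angle, 4), dtype=np.int32)
    for j, ia in enumerate(angles):
        idx4, w4 = _bilinear_terms(all_angles[ia], us, ts, shape2, vsz)
        data[j] = w4.T
        cols[j] = idx4.T
    indptr = np.arange(n_rows + 1, dtype=np.int64) * 4
    G = sp.csr_matrix((data.ravel(), cols.ravel(), indptr),
                      shape=(n_rows, ny * nx))
    GT = G.T.tocsr()
    entry = (G, GT, us, ts, dt)
    _CACHE[key] = entry
    while len(_CACHE) > _CACHE_MAX:
        _CACHE.popitem(last=False)
    return entry


def _as_slices(values: np.ndarray) -> Tuple[np.ndarray, bool]:
    """View a 2-D or 3-D volume as (ny*nx, nz); returns (flat, was_3d)."""
    if values.ndim == 2:
        return values.reshape(-1, 1), False
    return values.reshape(values.shape[0], -1).T.copy(), True


def project_array(values: np.ndarray, voxel_size_mm, scanner: ScannerModel,
                  angle_indices=None, kernel: Optional[TofKernel] = None) -> np.ndarray:
    """Array-level projector. Output axes: (angle, radial[, z][, tof])."""
    values = np.asarray(values, dtype=float)
    vsz = _vsz_shape(values.shape, voxel_size_mm)
    G, GT, us, ts, dt = _geometry(scanner, values.shape, vsz, angle_indices)
    flat, was_3d = _as_slices(values)
    nz = flat.shape[1]
    A = G.shape[0] // (len(us) * len(ts))
    R, S = len(us), len(ts)
    dtcm = dt / MM_PER_CM
    samp = G @ flat  # (A*R*S, nz)
    if kernel is not None:
        K = kernel.weights(ts)  # (S, T)
        T = K.shape[1]
        out = np.tensordot(samp.reshape(A * R, S, nz), K, axes=([1], [0]))
        out = out.reshape(A, R, nz, T) * dtcm
        if not was_3d:
            out = out[:, :, 0, :]
    else:
        out = samp.reshape(A, R, S, nz).sum(axis=2) * dtcm
        if not was_3d:
            out = out[:, :, 0]
    return out


def backproject_array(sino: np.ndarray, grid_shape, voxel_size_mm,
                      scanner: ScannerModel, angle_indices=None,
                      kernel: Optional[TofKernel] = None) -> np.ndarray:
    """Exact adjoint of :func:`project_array` (same sampling, same weights)."""
    sino = np.asarray(sino, dtype=float)
    grid_shape = tuple(grid_shape)
    vsz = _vsz_shape(grid_shape, voxel_size_mm)
    G, GT, us, ts, dt = _geometry(scanner, grid_shape, vsz, angle_indices)
    R, S = len(us), len(ts)
    A = G.shape[0] // (R * S)
    nz = grid_shape[0] if len(grid_shape) == 3 else 1
    dtcm = dt / MM_PER_CM
    sview = sino
    if len(grid_shape) == 2:
        sview = sino[:, :, None, ...] if kernel is not None else sino[:, :, None]
    if kernel is not None:
        if sview.ndim != 4:
            raise ValidationError("TOF sinogram shape inconsistent with grid")
        K = kernel.weights(ts)
        # (A,R,nz,T) x (S,T) -> (A,R,nz,S) -> (A,R,S,nz)
        vals = np.tensordot(sview, K, axes=([3], [1])).transpose(0, 1, 3, 2)
    else:
        if sview.ndim != 3:
            raise ValidationError("sinogram shape inconsistent with grid")
        vals = np.broadcast_to(sview[:, :, None, :], (A, R, S, nz))
    vals = np.ascontiguousarray(vals.reshape(A * R * S, nz)) * dtcm
    out_flat = GT @ vals  # (ny*nx, nz)
    ny, nx = grid_shape[-2:]
    if len(grid_shape) == 3:
        return out_flat.T.reshape(grid_shape)
    return out_flat[:, 0].reshape(ny, nx)


# ---------------------------------------------------------------- public API

def project(volume: VoxelVolume, scanner: ScannerModel,
            angle_indices=None) -> Sinogram:
    """Line integrals of a volume: units value * cm; linear in the input."""
    if volume.role not in ("mu_map", "activity"):
        raise ValidationError("project expects a mu_map or activity volume")
    vals = project_array(volume.values, volume.voxel_size_mm, scanner,
                         angle_indices)
    return Sinogram(vals, "line_integral",
                    scanner=scanner if angle_indices is None else None,
                    energy_kev=volume.energy_kev)


def backproject(sino: Sinogram, scanner: ScannerModel, grid_shape,
                voxel_size_mm, angle_indices=None) -> VoxelVolume:
    """Exact adjoint of :func:`project` on the same discretisation."""
    vals = backproject_array(sino.values, tuple(grid_shape), voxel_size_mm,
                             scanner, angle_indices)
    return VoxelVolume(vals, _vsz_shape(tuple(grid_shape), voxel_size_mm),
                       "activity")


def attenuation_factors(mu: VoxelVolume, scanner: ScannerModel,
                        angle_indices=None) -> Sinogram:
    """Per-LOR survival factors ``a_i = exp(-integral mu dl)`` in (0, 1]."""
    if mu.role != "mu_map":
        raise ValidationError("attenuation_factors expects a mu_map volume")
    if np.any(mu.values < 0):
        raise ValidationError("mu-map must be non-negative")
    line = project_array(mu.values, mu.voxel_size_mm, scanner, angle_indices)
    return Sinogram(np.exp(-line), "attenuation_factor",
                    scanner=scanner if angle_indices is None else None,
                    energy_kev=mu.energy_kev)


def project_tof(activity: VoxelVolume, scanner: ScannerModel,
                kernel: TofKernel, angle_indices=None) -> Sinogram:
    """TOF-resolved line integrals; summing over TOF bins equals project()."""
    if np.any(activity.values < 0):
        raise ValidationError("activity must be non-negative")
    vals = project_array(activity.values, activity.voxel_size_mm, scanner,
                         angle_indices, kernel=kernel)
    return Sinogram(vals, "line_integral", has_tof=True,
                    scanner=scanner if angle_indices is None else None)


def backproject_tof(sino: Sinogram, scanner: ScannerModel, kernel: TofKernel,
                    grid_shape, voxel_size_mm, angle_indices=None) -> VoxelVolume:
    """Exact adjoint of :func:`project_tof`."""
    vals = backproject_array(sino.values, tuple(grid_shape), voxel_size_mm,
                             scanner, angle_indices, kernel=kernel)
    return VoxelVolume(vals, _vsz_shape(tuple(grid_shape), voxel_size_mm),
                       "activity")
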