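"""Patch extraction, per-volume normalisation, and geometric augmentation."""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np
from scipy.ndimage import affine_transform

from ..core import ValidationError, substream


@dataclass(frozen=True)
class NormStats:
    mean: float
    std: float


def normalize(values: np.ndarray) -> Tuple[np.ndarray, NormStats]:
    """Z-score a volume to zero mean, unit variance; keep stats to invert."""
    values = np.asarray(values, dtype=float)
    mean = float(values.mean())
    std = float(values.std())
    if std == 0:
        raise ValidationError("cannot normalize a constant volume")
    return (values - mean) / std, NormStats(mean, std)


def denormalize(values: np.ndarray, stats: NormStats) -> np.ndarray:
    return np.asarray(values) * stats.std + stats.mean


def sample_patches(input_vol: np.ndarray, target_vol: np.ndarray,
                   patch_size: int, n_patches: int, seed: int,
                   body_threshold: float = 1e-4, min_body_frac: float = 0.5,
                   max_tries: int = 50) -> Tuple[np.ndarray, np.ndarray]:
    """Paired random patches at identical coordinates.

    Patches are drawn preferentially from the body: a candidate is accepted
    if at least ``min_body_frac`` of its input voxels exceed
    ``body_threshold``; after ``max_tries`` rejections the candidate is
    accepted anyway (a mostly-air volume should not dead-lock sampling).
    """
    input_vol = np.asarray(input_vol, dtype=float)
    target_vol = np.asarray(target_vol, dtype=float)
    if input_vol.shape != target_vol.shape:
        raise ValidationError("input/target grids differ")
    if any(s < patch_size for s in input_vol.shape):
        raise ValidationError(
            f"volume {input_vol.shape} smaller than patch size {patch_size}")
    rng = substream(seed, "patches")
    starts_max = [s - patch_size for s in input_vol.shape]
    xs, ys = [], []
    for _ in range(n_patches):
        for attempt in range(max_tries):
            start = tuple(int(rng.integers(0, m + 1)) for m in starts_max)
            sl = tuple(slice(s, s + patch_size) for s in start)
            xp = input_vol[sl]
            if (xp > body_threshold).mean() >= min_body_frac or \
                    attempt == max_tries - 1:
                xs.append(xp.copy())
                ys.append(target_vol[sl].copy())
                break
    return np.stack(xs), np.stack(ys)


@dataclass(frozen=True)
class AugmentRanges:
    """Geometric augmentation: zoom in 1 +/- scale, rotation in +/- degrees."""

    scale: float = 0.2
    rotation_deg: float = 10.0

    def __post_init__(self):
        if not 0 <= self.scale < 1:
            raise ValidationError("scale range must be in [0, 1)")
        if self.rotation_deg < 0:
            raise ValidationError("rotation range must be non-negative")


def _affine_about_center(patch: np.ndarray, matrix: np.ndarray,
                         order: int = 3) -> np.ndarray:
    center = (np.asarray(patch.shape) - 1) / 2.0
    offset = center - matrix @ center
    return affine_transform(patch, matrix, offset=offset, order=order,
                            mode="constant", cval=0.0)


def _rotation_matrix(ndim: int, theta_rad: float) -> np.ndarray:
    # rotation in the last two (transaxial) axes
    m = np.eye(ndim)
    c, s = np.cos(theta_rad), np.sin(theta_rad)
    m[-2:, -2:] = [[c, -s], [s, c]]
    return m


def augment(input_patch: np.ndarray, target_patch: np.ndarray,
            ranges: AugmentRanges, seed: int, order: int = 3
            ) -> Tuple[np.ndarray, np.ndarray]:
    """Apply one shared random zoom + rotation to both patch members.

    The scaling is geometric (resampling), not an intensity change: a
    uniform patch keeps its value. Zero ranges are the identity.
    """
    if ranges.scale == 0 and ranges.rotation_deg == 0:
        return input_patch, target_patch
    rng = substream(seed, "augment")
    s = 1.0 + ranges.scale * rng.uniform(-1, 1)
    theta = np.deg2rad(ranges.rotation_deg * rng.uniform(-1, 1))
    # affine_transform maps output coords through the matrix to input coords:
    # for zoom s the output-to-input matrix is diag(1/s)
    m = _rotation_matrix(input_patch.ndim, theta) / s
    return (_affine_about_center(np.asarray(input_patch, float), m, order),
            _affine_about_center(np.asarray(target_patch, float), m, order))


def tile_starts(size: int, patch: int, stride: int) -> List[int]:
    """Start offsets covering [0, size) with a final flush tile."""
    if size <= patch:
        return [0]
    starts = list(range(0, size - patch + 1, stride))
    if starts[-1] != size - patch:
        starts.append(size - patch)
    return starts


def blend_window(patch_size: int, ndim: int) -> np.ndarray:
    """Separable raised-cosine (Hann) blending window, strictly positive."""
    w1 = np.hanning(patch_size + 2)[1:-1]
    w1 = np.clip(w1, 1e-3, None)
    w = w1
    for _ in range(ndim - 1):
        w = np.multiply.outer(w, w1)
    return w
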