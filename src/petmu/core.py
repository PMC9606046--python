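"""Core containers: voxel volumes and sinograms.

Conventions
-----------
* Volumes are 2-D ``(ny, nx)`` (one transaxial slice, the default working
  dimensionality) or 3-D ``(nz, ny, nx)``.
* Sinograms are ``(n_angles, n_radial)`` for 2-D volumes and
  ``(n_angles, n_radial, nz)`` for 3-D volumes; a time-of-flight axis, when
  present, is appended last.
* Linear attenuation coefficients (LAC) are in cm^-1; line integrals are
  dimensionless after multiplying by path length in cm; activity is in Bq/mL.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

VOLUME_ROLES = ("mu_map", "activity", "hu", "label")
SINO_CONTENT = ("line_integral", "attenuation_factor", "counts", "acf")


class ValidationError(ValueError):
    """Raised when a container or operation input violates its contract."""


class ConfigurationError(ValueError):
    """Raised when a configuration is inconsistent (unknown tissue, bad geometry...)."""


@dataclass
class VoxelVolume:
    """A regular voxel grid with physical voxel size.

    Parameters
    ----------
    values
        2-D ``(ny, nx)`` or 3-D ``(nz, ny, nx)`` array.
    voxel_size_mm
        Per-axis voxel size in mm, matching ``values.ndim``.
    role
        One of ``mu_map``, ``activity``, ``hu``, ``label``.
    energy_kev
        Photon energy of a mu-map; required iff ``role == "mu_map"``.
    """

    values: np.ndarray
    voxel_size_mm: tuple
    role: str = "mu_map"
    energy_kev: Optional[float] = None

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim not in (2, 3):
            raise ValidationError(f"volume must be 2-D or 3-D, got ndim={self.values.ndim}")
        if np.isscalar(self.voxel_size_mm):
            self.voxel_size_mm = (float(self.voxel_size_mm),) * self.values.ndim
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)
        if len(self.voxel_size_mm) != self.values.ndim:
            raise ValidationError("voxel_size_mm must match volume dimensionality")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValidationError("voxel sizes must be positive")
        if self.role not in VOLUME_ROLES:
            raise ValidationError(f"unknown volume role {self.role!r}")
        if self.role == "mu_map":
            if self.energy_kev is None:
                raise ValidationError("mu_map volumes must carry energy_kev")
            if np.any(self.values < 0):
                raise ValidationError("mu_map values must be non-negative")
        elif self.energy_kev is not None:
            raise ValidationError("energy_kev only applies to mu_map volumes")

    @property
    def ndim(self) -> int:
        return self.values.ndim

    @property
    def shape(self) -> tuple:
        return self.values.shape

    def with_values(self, values: np.ndarray, role: Optional[str] = None,
                    energy_kev: Optional[float] = "keep") -> "VoxelVolume":
        """Return a copy carrying new values (and optionally a new role/energy)."""
        role = self.role if role is None else role
        if energy_kev == "keep":
            energy_kev = self.energy_kev if role == "mu_map" else None
        return VoxelVolume(np.asarray(values), self.voxel_size_mm, role, energy_kev)


@dataclass
class Sinogram:
    """Projection-space array with a content tag and optional TOF axis."""

    values: np.ndarray
    content: str
    has_tof: bool = False
    scanner: object = None  # ScannerModel reference, optional
    energy_kev: Optional[float] = None

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.content not in SINO_CONTENT:
            raise ValidationError(f"unknown sinogram content {self.content!r}")
        min_nd = 3 if self.has_tof else 2
        if self.values.ndim < min_nd or self.values.ndim > min_nd + 1:
            raise ValidationError(
                f"sinogram ndim {self.values.ndim} inconsistent with has_tof={self.has_tof}")
        if self.content in ("attenuation_factor", "acf"):
            if np.any(self.values <= 0) or np.any(self.values > 1 + 1e-12):
                raise ValidationError("attenuation factors must lie in (0, 1]")
        if self.content == "counts" and np.any(self.values < 0):
            raise ValidationError("counts must be non-negative")
        if self.scanner is not None:
            if self.values.shape[0] != self.scanner.n_angles or \
                    self.values.shape[1] != self.scanner.n_radial:
                raise ValidationError("sinogram shape inconsistent with scanner geometry")

    @property
    def shape(self) -> tuple:
        return self.values.shape

    def with_values(self, values, content: Optional[str] = None,
                    has_tof: Optional[bool] = None) -> "Sinogram":
        return Sinogram(np.asarray(values),
                        self.content if content is None else content,
                        self.has_tof if has_tof is None else has_tof,
                        self.scanner, self.energy_kev)


def check_same_grid(a: VoxelVolume, b: VoxelVolume) -> None:
    if a.shape != b.shape:
        raise ValidationError(f"grid mismatch: {a.shape} vs {b.shape}")
    if not np.allclose(a.voxel_size_mm, b.voxel_size_mm):
        raise ValidationError("voxel size mismatch")


def substream(seed: int, *tags: object) -> np.random.Generator:
    """Named random substream derived from a single global seed.

    All randomness in the package flows from one seed through these named
    substreams, so pipeline stages are individually reproducible.
    """
    import zlib

    entropy = [int(seed)] + [zlib.crc32(str(t).encode()) % (2 ** 31) for t in tags]
    return np.random.default_rng(np.random.SeedSequence(entropy))
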