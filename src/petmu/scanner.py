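"""Scanner model: parallel-beam geometry, TOF kernel, energy windows, blank rates.

The scanner emulates a long axial field-of-view TOF-PET system whose
lutetium-based (LSO) scintillators provide an intrinsic transmission source:
Lu-176 decays emit gammas at 307, 202 and 88 keV, and events collected in two
energy windows (275-355 keV and 165-247 keV) form transmission sinograms at
effective energies of 307 and 202 keV. Emission data are acquired with an open
energy window (160-725 keV) and a 6.64 ns coincidence window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple

import numpy as np

from .core import ConfigurationError, ValidationError

# speed of light in mm per picosecond
C_MM_PER_PS = 0.299792458
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # sigma = FWHM / 2.3548


@dataclass(frozen=True)
class ScannerModel:
    """Geometry and acquisition constants of the simulated scanner.

    ``blank_rate`` maps a transmission-window energy (keV of the dominant
    Lu-176 line) to the expected unattenuated count rate per line of response
    in counts/s. The defaults are chosen so a 5-minute transmission scan is
    visibly noisy but reconstructable; they are a simulation setting, not a
    measured property of any physical scanner.
    """

    n_angles: int = 96
    n_radial: int = 64
    fov_mm: float = 105.6
    n_tof_bins: int = 7
    tof_fwhm_ps: float = 225.0
    coincidence_window_ns: float = 6.64
    open_energy_window_kev: Tuple[float, float] = (160.0, 725.0)
    tx_windows_kev: Tuple[Tuple[float, float], Tuple[float, float]] = (
        (275.0, 355.0), (165.0, 247.0))
    blank_rate: Tuple[Tuple[float, float], ...] = ((307.0, 1.4), (202.0, 0.9))

    def __post_init__(self):
        if self.n_angles < 1 or self.n_radial < 1:
            raise ValidationError("n_angles and n_radial must be >= 1")
        if self.tof_fwhm_ps <= 0:
            raise ValidationError("tof_fwhm_ps must be positive")
        if self.fov_mm <= 0:
            raise ValidationError("fov_mm must be positive")
        for lo, hi in self.tx_windows_kev:
            if not lo < hi:
                raise ValidationError("tx energy windows must be ordered low < high")
        lo, hi = self.open_energy_window_kev
        if not lo < hi:
            raise ValidationError("open energy window must be ordered low < high")
        if any(r < 0 for _, r in self.blank_rate):
            raise ValidationError("blank rates must be non-negative")

    @property
    def angles_rad(self) -> np.ndarray:
        return np.arange(self.n_angles) * np.pi / self.n_angles

    @property
    def radial_spacing_mm(self) -> float:
        return self.fov_mm / self.n_radial

    @property
    def tx_energies_kev(self) -> Tuple[float, ...]:
        return tuple(e for e, _ in self.blank_rate)

    def blank_rate_at(self, energy_kev: float) -> float:
        for e, r in self.blank_rate:
            if abs(e - energy_kev) < 1e-9:
                return r
        raise ConfigurationError(f"no blank rate configured for {energy_kev} keV")

    def tx_energy_for_window(self, window_kev: Tuple[float, float]) -> float:
        """Map a transmission energy window to its Lu-176 line energy."""
        for (lo, hi), energy in zip(self.tx_windows_kev, (307.0, 202.0)):
            if abs(lo - window_kev[0]) < 1e-9 and abs(hi - window_kev[1]) < 1e-9:
                return energy
        raise ConfigurationError(f"unknown transmission window {window_kev}")

    @classmethod
    def for_grid(cls, shape, voxel_size_mm=1.65, **kw) -> "ScannerModel":
        """Scanner whose radial sampling matches a given reconstruction grid."""
        ny, nx = shape[-2:]
        if np.isscalar(voxel_size_mm):
            vy = vx = float(voxel_size_mm)
        else:
            vy, vx = voxel_size_mm[-2:]
        n_radial = max(ny, nx)
        fov = n_radial * max(vy, vx)
        kw.setdefault("n_radial", n_radial)
        kw.setdefault("fov_mm", fov)
        kw.setdefault("n_angles", int(np.ceil(np.pi / 2 * n_radial / 16)) * 16)
        return cls(**kw)


@dataclass(frozen=True)
class TofKernel:
    """Gaussian time-of-flight localisation kernel, discretised over TOF bins.

    The annihilation position offset along a line of response is
    ``c * dt / 2`` for an arrival-time difference ``dt``, so the spatial FWHM
    of the kernel is ``c * tof_fwhm_ps / 2`` in mm. The kernel is truncated at
    3 sigma and renormalised per source position so its weights always sum to
    one inside the field of view.
    """

    fwhm_ps: float = 225.0
    bin_width_mm: float = 30.0
    n_bins: int = 7

    def __post_init__(self):
        if self.fwhm_ps <= 0 or self.bin_width_mm <= 0 or self.n_bins < 1:
            raise ValidationError("TofKernel parameters must be positive")

    @property
    def sigma_mm(self) -> float:
        return C_MM_PER_PS * self.fwhm_ps / 2.0 * FWHM_TO_SIGMA

    @property
    def bin_centers_mm(self) -> np.ndarray:
        return (np.arange(self.n_bins) - (self.n_bins - 1) / 2.0) * self.bin_width_mm

    def weights(self, offsets_mm: np.ndarray) -> np.ndarray:
        """Per-bin weights for source positions at signed ray offsets (mm).

        Returns an array of shape ``offsets_mm.shape + (n_bins,)`` whose rows
        sum to one. Raises if any offset is not covered by the bin range
        (within the 3-sigma truncation), i.e. the kernel does not cover the
        field of view.
        """
        offsets_mm = np.asarray(offsets_mm, dtype=float)
        d = offsets_mm[..., None] - self.bin_centers_mm
        sig = self.sigma_mm
        w = np.exp(-0.5 * (d / sig) ** 2)
        w[np.abs(d) > 3.0 * sig + self.bin_width_mm / 2.0] = 0.0
        norm = w.sum(axis=-1, keepdims=True)
        if np.any(norm == 0):
            raise ConfigurationError(
                "TOF kernel bins do not cover the field of view; "
                "increase n_bins or bin_width_mm")
        return w / norm

    @classmethod
    def for_scanner(cls, scanner: ScannerModel, bin_width_mm: float = 30.0) -> "TofKernel":
        """Kernel with enough bins to cover the scanner's transaxial FOV diagonal."""
        half_span = scanner.fov_mm * np.sqrt(2.0) / 2.0
        sigma = C_MM_PER_PS * scanner.tof_fwhm_ps / 2.0 * FWHM_TO_SIGMA
        n = int(np.ceil(2 * (half_span + 3 * sigma) / bin_width_mm))
        n = max(n, scanner.n_tof_bins)
        if n % 2 == 0:
            n += 1
        return cls(fwhm_ps=scanner.tof_fwhm_ps, bin_width_mm=bin_width_mm, n_bins=n)
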