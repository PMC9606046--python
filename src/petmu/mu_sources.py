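"""Candidate mu-map sources other than joint estimation.

* ``hu_to_mu`` — the standard bilinear CT conversion: Hounsfield units map to
  511 keV LAC piecewise-linearly with a breakpoint at water (0 HU), anchored
  so air (-1000 HU) maps to zero.
* ``map_energy`` — scale a transmission-energy mu-map (202 or 307 keV, the
  Lu-176 lines) to 511 keV with a two-segment multiplicative model: a
  soft-tissue segment and a bone segment split at a LAC breakpoint, because
  bone's photoelectric cross-section makes a single global scale wrong at
  the lower energies.
* ``fuse_tx_mu`` — unweighted voxelwise mean of the two mapped transmission
  mu-maps followed by Gaussian smoothing (default FWHM 4 mm).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.ndimage import gaussian_filter

from .core import ValidationError, VoxelVolume, check_same_grid
from .phantom import TissueTable, default_tissue_table
from .scanner import FWHM_TO_SIGMA


@dataclass(frozen=True)
class BilinearParams:
    """Piecewise-linear HU -> LAC(511 keV) conversion parameters.

    The segment below the breakpoint is fixed by the air and water anchors:
    slope_below = water_lac / (breakpoint_hu + 1000). Values below are the
    widely used soft-tissue/bone form with the breakpoint at water.
    """

    breakpoint_hu: float = 0.0
    slope_above: float = 5.1e-5      # cm^-1 per HU above the breakpoint
    water_lac: float = 0.096         # cm^-1 at 511 keV

    @property
    def slope_below(self) -> float:
        return self.water_lac / (self.breakpoint_hu + 1000.0)


def hu_to_mu(hu: VoxelVolume, params: BilinearParams = BilinearParams()
             ) -> VoxelVolume:
    """Bilinear HU -> 511 keV LAC conversion; monotone, clipped at zero."""
    if hu.role != "hu":
        raise ValidationError("hu_to_mu expects an HU volume")
    v = np.clip(np.asarray(hu.values, dtype=float), -1024.0, None)
    bp = params.breakpoint_hu
    mu_bp = params.slope_below * (bp + 1000.0)  # == water_lac at bp = 0
    mu = np.where(v <= bp,
                  params.slope_below * (v + 1000.0),
                  mu_bp + params.slope_above * (v - bp))
    return VoxelVolume(np.clip(mu, 0.0, None), hu.voxel_size_mm, "mu_map", 511.0)


@dataclass(frozen=True)
class EnergyMapParams:
    """Two-segment multiplicative scaling from a source energy to 511 keV.

    ``mu511 = soft_scale * mu``                          for mu <= breakpoint
    ``mu511 = soft_scale * bp + bone_scale * (mu - bp)`` for mu > breakpoint

    which is continuous at the breakpoint and zero-preserving.
    """

    source_energy_kev: float
    soft_scale: float
    bone_scale: float
    breakpoint_lac: float

    def __post_init__(self):
        if self.soft_scale <= 0 or self.bone_scale <= 0:
            raise ValidationError("scale factors must be positive")
        if self.breakpoint_lac < 0:
            raise ValidationError("breakpoint must be non-negative")

    @classmethod
    def from_tissue_table(cls, energy_kev: float,
                          table: Optional[TissueTable] = None,
                          breakpoint_lac: Optional[float] = None
                          ) -> "EnergyMapParams":
        """Derive segment scales so water and bone map exactly.

        Default breakpoints: 0.18 cm^-1 at 202 keV and 0.15 cm^-1 at 307 keV
        (bone LAC at 307 keV is ~0.176 cm^-1, so the breakpoint must sit
        below it for the bone segment to be reachable).
        """
        if energy_kev == 511.0:
            return cls(511.0, 1.0, 1.0, breakpoint_lac or 1.0)
        if energy_kev not in (202.0, 307.0):
            raise ValidationError(f"unsupported source energy {energy_kev} keV")
        table = table or default_tissue_table()
        if breakpoint_lac is None:
            breakpoint_lac = {202.0: 0.18, 307.0: 0.15}[energy_kev]
        w_src = table.lac("soft_tissue", energy_kev)
        w_511 = table.lac("soft_tissue", 511.0)
        b_src = table.lac("bone", energy_kev)
        b_511 = table.lac("bone", 511.0)
        soft = w_511 / w_src
        if b_src <= breakpoint_lac:
            raise ValidationError(
                "breakpoint must lie below the bone LAC at the source energy")
        bone = (b_511 - soft * breakpoint_lac) / (b_src - breakpoint_lac)
        return cls(energy_kev, soft, bone, breakpoint_lac)


def map_energy(mu_e: VoxelVolume, params: Optional[EnergyMapParams] = None
               ) -> VoxelVolume:
    """Map a mu-map at 202/307 keV to 511 keV (two-segment scaling)."""
    if mu_e.role != "mu_map":
        raise ValidationError("map_energy expects a mu_map volume")
    if params is None:
        params = EnergyMapParams.from_tissue_table(mu_e.energy_kev)
    if abs(params.source_energy_kev - mu_e.energy_kev) > 1e-6:
        raise ValidationError("params do not match the mu-map's energy")
    v = np.asarray(mu_e.values, dtype=float)
    bp = params.breakpoint_lac
    out = np.where(v <= bp,
                   params.soft_scale * v,
                   params.soft_scale * bp + params.bone_scale * (v - bp))
    return VoxelVolume(np.clip(out, 0.0, None), mu_e.voxel_size_mm,
                       "mu_map", 511.0)


def fuse_tx_mu(mu_from_307: VoxelVolume, mu_from_202: VoxelVolume,
               fwhm_mm: float = 4.0, weights=(0.5, 0.5)) -> VoxelVolume:
    """Average two 511 keV transmission mu-maps and smooth (FWHM in mm).

    The default is the unweighted mean; smoothing uses a Gaussian with
    sigma = fwhm / (2 sqrt(2 ln 2)) per axis, reflective boundaries.
    """
    for m in (mu_from_307, mu_from_202):
        if m.role != "mu_map" or abs((m.energy_kev or 0) - 511.0) > 1e-6:
            raise ValidationError("fuse_tx_mu expects 511 keV mu-maps")
    check_same_grid(mu_from_307, mu_from_202)
    if fwhm_mm < 0:
        raise ValidationError("fwhm_mm must be non-negative")
    w1, w2 = weights
    fused = (w1 * mu_from_307.values + w2 * mu_from_202.values) / (w1 + w2)
    if fwhm_mm > 0:
        sigmas = [fwhm_mm * FWHM_TO_SIGMA / v for v in mu_from_307.voxel_size_mm]
        fused = gaussian_filter(fused, sigmas, mode="reflect")
    return VoxelVolume(np.clip(fused, 0.0, None), mu_from_307.voxel_size_mm,
                       "mu_map", 511.0)
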