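"""Poisson count simulation for LSO-background transmission and TOF emission.

Transmission: the intrinsic Lu-176 radiation of the scintillators acts as a
distributed transmission source. We model it as parallel-beam transmission
with a blank (unattenuated) rate per line of response: counts in window W are
Poisson with mean ``blank_rate(W) * duration * exp(-P mu_E)`` where ``mu_E``
is the mu-map at the window's effective gamma energy. A post-injection scan
can additionally see contamination from the PET tracer, modelled as an
additive rate proportional to the body-activity line integral (an explicit,
configurable model — the physical leakage mechanism is scanner-specific).

Emission: TOF counts are Poisson with mean
``duration * sens * [a_i (P lambda)_it + s_it + r_it]`` — attenuated trues
plus a smooth TOF-uniform scatter term (scaled to a target scatter fraction)
plus uniform randoms. The additive terms are returned alongside the counts:
scatter estimation is out of scope here, so the reconstruction modules take
the additive background as known, keeping the likelihood model faithful.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .core import Sinogram, ValidationError, VoxelVolume, substream
from .projector import attenuation_factors, project, project_tof
from .scanner import ScannerModel, TofKernel

#: counts per (Bq/mL * cm) per second per LOR; sets emission count statistics
DEFAULT_EMISSION_SENSITIVITY = 2e-4


def simulate_transmission(mu_at_E: VoxelVolume, scanner: ScannerModel,
                          window_kev: Tuple[float, float], duration_s: float,
                          seed: Optional[int] = None, noiseless: bool = False,
                          contamination: Optional[np.ndarray] = None
                          ) -> Tuple[Sinogram, Sinogram]:
    """Simulate one LSO-TX window; returns (counts, blank) sinograms.

    ``contamination`` is an optional additive mean (counts) added to the
    Poisson mean, e.g. tracer leakage into the window for a post-injection
    scan. The blank sinogram returned is the noiseless blank mean.
    """
    if duration_s <= 0:
        raise ValidationError("duration_s must be positive")
    energy = scanner.tx_energy_for_window(tuple(window_kev))
    if mu_at_E.energy_kev is None or abs(mu_at_E.energy_kev - energy) > 1e-6:
        raise ValidationError(
            f"mu-map energy {mu_at_E.energy_kev} does not match window "
            f"energy {energy} keV")
    rate = scanner.blank_rate_at(energy)
    blank = np.full((scanner.n_angles, scanner.n_radial), rate * duration_s)
    acf = attenuation_factors(mu_at_E, scanner).values
    mean = blank * acf
    if contamination is not None:
        contamination = np.asarray(contamination, dtype=float)
        if contamination.shape != mean.shape or np.any(contamination < 0):
            raise ValidationError("contamination must be a non-negative sinogram")
        mean = mean + contamination
    if noiseless:
        counts = mean
    else:
        rng = substream(0 if seed is None else seed, "tx", energy)
        counts = rng.poisson(mean).astype(float)
    return (Sinogram(counts, "counts", scanner=scanner, energy_kev=energy),
            Sinogram(blank, "counts", scanner=scanner, energy_kev=energy))


def tx_contamination_mean(activity: VoxelVolume, scanner: ScannerModel,
                          window_kev: Tuple[float, float], duration_s: float,
                          fraction: float = 0.05) -> np.ndarray:
    """Post-injection contamination mean for a transmission window.

    A TOF-less additive term proportional to the body-activity line integral,
    scaled so its maximum equals ``fraction`` of the blank counts. This is a
    deliberately simple leakage model; ``fraction=0`` recovers a clean
    pre-injection scan.
    """
    if not 0 <= fraction < 1:
        raise ValidationError("contamination fraction must be in [0, 1)")
    energy = scanner.tx_energy_for_window(tuple(window_kev))
    blank_counts = scanner.blank_rate_at(energy) * duration_s
    line = project(activity, scanner).values
    peak = line.max()
    if peak <= 0 or fraction == 0:
        return np.zeros_like(line)
    return fraction * blank_counts * line / peak


@dataclass
class EmissionSim:
    """Simulated TOF emission data with its known additive background."""

    counts: Sinogram          # Poisson counts (or mean if noiseless)
    additive: Sinogram        # known scatter + randoms mean, counts domain
    mean_trues: Sinogram      # attenuated trues mean, counts domain
    acf: Sinogram             # true attenuation factors at 511 keV


def simulate_emission(activity: VoxelVolume, mu_511: VoxelVolume,
                      scanner: ScannerModel, kernel: TofKernel,
                      duration_s: float, scatter_fraction: float = 0.0,
                      randoms_rate: float = 0.0, seed: Optional[int] = None,
                      noiseless: bool = False,
                      sensitivity: float = DEFAULT_EMISSION_SENSITIVITY
                      ) -> EmissionSim:
    """Simulate TOF emission counts for an activity/mu-map pair.

    The mean model is ``duration * [a_i (P lambda)_it + s_it + r_it]`` with
    the trues scaled by ``sensitivity``; scatter is a radially smoothed,
    TOF-uniform background normalised so scatter/(trues+scatter) equals
    ``scatter_fraction``; randoms contribute ``randoms_rate`` counts/s per
    (LOR, TOF bin) uniformly.
    """
    if duration_s <= 0:
        raise ValidationError("duration_s must be positive")
    if not 0 <= scatter_fraction < 1:
        raise ValidationError("scatter_fraction must be in [0, 1)")
    if randoms_rate < 0:
        raise ValidationError("randoms_rate must be non-negative")
    if np.any(activity.values < 0):
        raise ValidationError("activity must be non-negative")
    if mu_511.energy_kev is None or abs(mu_511.energy_kev - 511.0) > 1e-6:
        raise ValidationError("emission simulation needs the 511 keV mu-map")

    acf = attenuation_factors(mu_511, scanner)
    p_lam = project_tof(activity, scanner, kernel).values
    trues = duration_s * sensitivity * acf.values[..., None] * p_lam

    n_tof = trues.shape[-1]
    total_trues = trues.sum()
    if scatter_fraction > 0 and total_trues > 0:
        profile = trues.sum(axis=-1)  # (angle, radial[, z])
        smooth = gaussian_filter1d(profile, sigma=max(2.0, scanner.n_radial / 16),
                                   axis=1, mode="constant")
        scatter = np.repeat(smooth[..., None] / n_tof, n_tof, axis=-1)
        target = scatter_fraction / (1.0 - scatter_fraction) * total_trues
        scatter *= target / scatter.sum()
    else:
        scatter = np.zeros_like(trues)
    randoms = np.full_like(trues, randoms_rate * duration_s)
    additive = scatter + randoms
    mean = trues + additive

    if noiseless:
        counts = mean
    else:
        rng = substream(0 if seed is None else seed, "emission")
        counts = rng.poisson(mean).astype(float)

    mk = lambda v: Sinogram(v, "counts", has_tof=True, scanner=scanner)
    return EmissionSim(counts=mk(counts), additive=mk(additive),
                       mean_trues=mk(trues), acf=acf)
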