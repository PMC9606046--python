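"""Quantitative evaluation of mu-maps and PET images.

Implements the percentage relative mean error and relative mean absolute
error of an image against a reference,

    rME(%)  = 100 * mean[ (I_x - I_ref) / I_ref ]
    rMAE(%) = 100 * mean[ |I_x - I_ref| / I_ref ]

computed voxelwise over a volume of interest (VOI), LAC-threshold tissue
segmentation (fat 0.080-0.090, water-based soft tissue 0.090-0.105, bone
> 0.105 cm^-1, with hole filling to include marrow in bone), 50%-of-max
isocontour lesion masks, standardised uptake values, and tabular report
assembly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import ValidationError, VoxelVolume, check_same_grid

FAT_RANGE = (0.080, 0.090)      # cm^-1, half-open [lo, hi)
WATER_RANGE = (0.090, 0.105)    # cm^-1, closed [lo, hi]
BONE_THRESHOLD = 0.105          # cm^-1, exclusive


@dataclass
class VoiMask:
    mask: np.ndarray
    label: str
    provenance: str = "threshold"

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def _masked_ratio_terms(img, ref, mask, ref_floor):
    img = np.asarray(img.values if isinstance(img, VoxelVolume) else img, float)
    ref = np.asarray(ref.values if isinstance(ref, VoxelVolume) else ref, float)
    m = np.asarray(mask.mask if isinstance(mask, VoiMask) else mask, bool)
    if img.shape != ref.shape or m.shape != ref.shape:
        raise ValidationError("image/reference/mask grids differ")
    eff = m & (ref >= ref_floor) & (ref > 0)
    if not eff.any():
        raise ValidationError("mask is empty after the reference floor")
    return img[eff], ref[eff]


def rme(img, ref, mask, ref_floor: float = 0.0) -> float:
    """Percentage relative mean error over a VOI (voxelwise, then averaged)."""
    i, r = _masked_ratio_terms(img, ref, mask, ref_floor)
    return float(100.0 * np.mean((i - r) / r))


def rmae(img, ref, mask, ref_floor: float = 0.0) -> float:
    """Percentage relative mean absolute error over a VOI."""
    i, r = _masked_ratio_terms(img, ref, mask, ref_floor)
    return float(100.0 * np.mean(np.abs(i - r) / r))


def mu_ref_floor(ref: VoxelVolume, mask: np.ndarray, frac: float = 0.5) -> float:
    """Default reference floor for mu-map VOIs: frac * VOI median."""
    vals = ref.values[np.asarray(mask, bool)]
    if vals.size == 0:
        return 0.0
    return float(frac * np.median(vals))


def segment_tissues(mu_ref: VoxelVolume) -> Dict[str, VoiMask]:
    """Threshold segmentation of a 511 keV mu-map into fat/water/bone VOIs.

    Bone is thresholded at LAC > 0.105 cm^-1 and hole-filled per connected
    component so marrow is included; fat and water-based soft tissue are the
    LAC ranges [0.080, 0.090) and [0.090, 0.105], excluding bone-filled
    voxels.
    """
    if mu_ref.role != "mu_map":
        raise ValidationError("segment_tissues expects a mu-map")
    v = mu_ref.values
    bone_core = v > BONE_THRESHOLD
    bone = ndimage.binary_fill_holes(bone_core)
    fat = (v >= FAT_RANGE[0]) & (v < FAT_RANGE[1]) & ~bone
    water = (v >= WATER_RANGE[0]) & (v <= WATER_RANGE[1]) & ~bone
    return {
        "fat": VoiMask(fat, "fat"),
        "water": VoiMask(water, "water_soft_tissue"),
        "bone": VoiMask(bone, "bone"),
    }


def body_mask(mu_ref: VoxelVolume, threshold: float = 0.04,
              erode: int = 0) -> np.ndarray:
    """Body support of a mu-map (LAC above ~half lung), optionally eroded."""
    m = mu_ref.values > threshold
    if erode > 0:
        m = ndimage.binary_erosion(m, iterations=erode)
    return m


def isocontour_lesion(pet: VoxelVolume, seed_point: Sequence[int],
                      threshold_frac: float = 0.5) -> VoiMask:
    """Isocontour VOI: connected region >= frac * local max nearest the seed.

    The local maximum is found by greedy hill-climbing from the seed, so the
    mask tracks the lesion the seed points at even when brighter structures
    exist elsewhere.
    """
    v = np.asarray(pet.values, float)
    seed = tuple(int(s) for s in seed_point)
    if len(seed) != v.ndim or any(not 0 <= s < n for s, n in zip(seed, v.shape)):
        raise ValidationError("seed point outside the grid")
    if v[seed] <= 0:
        raise ValidationError("seed lies in a zero-activity region")
    # greedy ascent to the nearest local maximum
    pos = seed
    while True:
        best = pos
        for off in np.ndindex(*(3,) * v.ndim):
            cand = tuple(p + o - 1 for p, o in zip(pos, off))
            if all(0 <= c < n for c, n in zip(cand, v.shape)) and \
                    v[cand] > v[best]:
                best = cand
        if best == pos:
            break
        pos = best
    peak = v[pos]
    thresh = threshold_frac * peak
    region = v > thresh if threshold_frac > 0 else v > 0
    lab, _ = ndimage.label(region)
    return VoiMask(lab == lab[pos], "lesion", provenance="isocontour")


def suv(activity: VoxelVolume, injected_dose_bq: float,
        body_weight_g: float) -> VoxelVolume:
    """Standardised uptake value: concentration / (dose / weight).

    Activity concentration in Bq/mL and tissue density of 1 g/mL give the
    conventional dimensionless SUV.
    """
    if injected_dose_bq <= 0 or body_weight_g <= 0:
        raise ValidationError("dose and weight must be positive")
    if activity.role != "activity":
        raise ValidationError("suv expects an activity volume")
    return activity.with_values(
        activity.values / (injected_dose_bq / body_weight_g), role="activity")


@dataclass
class EvalReport:
    """Tabular rME/rMAE and SUV statistics for a set of comparisons."""

    table: pd.DataFrame
    metadata: Dict = field(default_factory=dict)

    def to_files(self, table_path, meta_path) -> None:
        import json

        self.table.to_csv(table_path, sep="\t", index=False, float_format="%.6g")
        with open(meta_path, "w") as fh:
            json.dump(self.metadata, fh, indent=2, default=str)


def build_report(volumes: Dict[str, VoxelVolume], reference: str,
                 masks: Dict[str, VoiMask],
                 ref_floor_frac: float = 0.5,
                 suv_params: Optional[Tuple[float, float]] = None,
                 metadata: Optional[Dict] = None) -> EvalReport:
    """rME/rMAE (and optional SUV) of every volume against the reference.

    ``volumes`` maps image tags to co-registered volumes; ``reference``
    names the entry used as I_ref. For mu-maps the reference floor is
    ``ref_floor_frac`` times the VOI median; for activity images voxels with
    non-positive reference are excluded.
    """
    if reference not in volumes:
        raise ValidationError(f"missing reference volume {reference!r}")
    ref = volumes[reference]
    rows = []
    for tag, vol in volumes.items():
        if tag == reference:
            continue
        check_same_grid(vol, ref)
        for voi_name, voi in masks.items():
            if voi.n_voxels == 0:
                continue
            if ref.role == "mu_map":
                floor = mu_ref_floor(ref, voi.mask, ref_floor_frac)
            else:
                floor = np.finfo(float).tiny
            row = {
                "image": tag, "reference": reference, "voi": voi_name,
                "n_voxels": voi.n_voxels,
                "rme_pct": rme(vol, ref, voi, floor),
                "rmae_pct": rmae(vol, ref, voi, floor),
            }
            if suv_params is not None and vol.role == "activity":
                dose, weight = suv_params
                s_img = suv(vol, dose, weight).values[voi.mask].mean()
                s_ref = suv(ref, dose, weight).values[voi.mask].mean()
                row["suv_mean"] = float(s_img)
                row["suv_ref_mean"] = float(s_ref)
                row["suv_abs_err_pct"] = float(
                    100.0 * abs(s_img - s_ref) / s_ref) if s_ref else np.nan
            rows.append(row)
    return EvalReport(pd.DataFrame(rows), metadata or {})
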