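"""Synthetic-cohort study: the desk-scale analogue of the patient study.

Builds a cohort of randomized body phantoms, carries each through the
transmission -> MLTR -> energy-mapping/fusion -> MLACF chain (optionally for
both pre- and post-injection transmission), cross-validates the enhancement
network over the cohort, and evaluates mu-maps and PET reconstructions
against the ground truth (which plays the role of the CT-derived reference).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import VoxelVolume, substream
from .enhance import UNetEnhancer, crossval, run_crossval
from .evaluate import body_mask, rmae, segment_tissues
from .phantom import Phantom, body_phantom_spec, build_phantom, \
    default_tissue_table
from .pipeline import RunConfig, _build_scanner, mlacf_mu_map, \
    reconstruct_pet, tx_mu_map
from .scanner import TofKernel


@dataclass
class CohortSubject:
    id: int
    phantom: Phantom
    mlacf_mu: Dict[str, VoxelVolume]   # mode ("pre"/"post") -> mu-map
    em: object                          # EmissionSim
    dl_mu: Dict[str, VoxelVolume] = field(default_factory=dict)


def build_cohort(n_subjects: int, seed: int, cfg: Optional[RunConfig] = None,
                 modes: Sequence[str] = ("post",)) -> List[CohortSubject]:
    """Generate phantoms and their MLACF mu-maps for the requested modes."""
    cfg = cfg or RunConfig()
    scanner = _build_scanner(cfg)
    kernel = TofKernel.for_scanner(scanner, cfg.scanner.tof_bin_width_mm)
    table = default_tissue_table()
    cohort = []
    for s in range(n_subjects):
        sub_seed = int(substream(seed, "subject", s).integers(2 ** 31))
        spec = body_phantom_spec(tuple(cfg.phantom.shape), seed=sub_seed,
                                 n_lesions=cfg.phantom.n_lesions,
                                 voxel_size_mm=cfg.phantom.voxel_size_mm)
        phantom = build_phantom(spec, table)
        entry = CohortSubject(s, phantom, {}, None)
        for mode in modes:
            mu_tx = tx_mu_map(phantom, scanner, cfg, sub_seed,
                              post_injection=(mode == "post"))
            result, em = mlacf_mu_map(phantom, scanner, kernel, cfg,
                                      sub_seed, mu_tx)
            entry.mlacf_mu[mode] = result.mu_map
            entry.em = em
        cohort.append(entry)
    return cohort


def body_rmae(pred: VoxelVolume, truth: VoxelVolume) -> float:
    """Body-VOI rMAE (%) of a mu-map against the ground truth."""
    return rmae(pred, truth, body_mask(truth, erode=1))


def default_cv_enhancer(fold: int, seed: int = 0) -> UNetEnhancer:
    """Small 2-D network used for desk-scale cross-validation."""
    return UNetEnhancer(levels=3, base_channels=8, patch_size=64, ndim=2,
                        epochs=30, batch_size=8, patches_per_volume=4,
                        seed=seed + fold)


def enhancement_crossval(cohort: Sequence[CohortSubject], k: int, seed: int,
                         mode: str = "post", enhancer_factory=None):
    """k-fold CV of the enhancement network over the cohort.

    Returns (plan, records); each record carries per-test-subject body rMAE
    of the MLACF input and the enhanced prediction, plus the fold estimator.
    Also attaches each subject's cross-validated prediction (made by the one
    fold where the subject is in the test set) to ``subject.dl_mu[mode]``.
    """
    factory = enhancer_factory or (lambda f: default_cv_enhancer(f, seed))
    inputs = {s.id: s.mlacf_mu[mode] for s in cohort}
    targets = {s.id: s.phantom.mu(511) for s in cohort}
    plan = crossval([s.id for s in cohort], k=k, seed=seed)
    records = run_crossval(inputs, targets, plan, factory, body_rmae)
    by_id = {s.id: s for s in cohort}
    for rec in records:
        est = rec["estimator"]
        for sid in rec["test_ids"]:
            by_id[sid].dl_mu[mode] = est.predict(inputs[sid])
    return plan, records


def apply_fold_models(cohort: Sequence[CohortSubject], records, mode: str):
    """Predict ``mode`` mu-maps for each subject with its own fold's model
    (the model that never saw the subject during training)."""
    by_id = {s.id: s for s in cohort}
    for rec in records:
        est = rec["estimator"]
        for sid in rec["test_ids"]:
            subj = by_id[sid]
            subj.dl_mu[mode] = est.predict(subj.mlacf_mu[mode])


def tissue_rmae_table(cohort: Sequence[CohortSubject], mode: str = "post"
                      ) -> Dict[str, Dict[str, float]]:
    """Per-tissue mean rMAE (%) of MLACF and enhanced mu-maps vs truth."""
    from .evaluate import mu_ref_floor

    acc = {"mlacf": {"fat": [], "water": [], "bone": []},
           "dl": {"fat": [], "water": [], "bone": []}}
    for s in cohort:
        truth = s.phantom.mu(511)
        masks = segment_tissues(truth)
        for tag, vol in (("mlacf", s.mlacf_mu[mode]), ("dl", s.dl_mu[mode])):
            for voi in ("fat", "water", "bone"):
                m = masks[voi]
                if m.n_voxels == 0:
                    continue
                floor = mu_ref_floor(truth, m.mask, 0.5)
                acc[tag][voi].append(rmae(vol, truth, m, floor))
    return {tag: {voi: float(np.mean(v)) for voi, v in vois.items() if v}
            for tag, vois in acc.items()}


def pet_study(cohort: Sequence[CohortSubject], cfg: Optional[RunConfig],
              mode: str = "post", suv_params: Tuple[float, float] = (2e8, 7e4)
              ) -> Dict[str, Dict[str, float]]:
    """Reconstruct PET with reference/MLACF/enhanced mu-maps and evaluate.

    Returns mean per-tissue PET rMAE for MLACF- and enhanced-mu images and
    mean absolute SUV error in the lesion isocontour VOI.
    """
    from .evaluate import isocontour_lesion

    cfg = cfg or RunConfig()
    scanner = _build_scanner(cfg)
    kernel = TofKernel.for_scanner(scanner, cfg.scanner.tof_bin_width_mm)
    acc = {"mlacf": {"fat": [], "water": [], "bone": []},
           "dl": {"fat": [], "water": [], "bone": []}}
    suv_err = {"mlacf": [], "dl": []}
    for s in cohort:
        truth = s.phantom.mu(511)
        masks = segment_tissues(truth)
        pet_ref = reconstruct_pet(s.em, truth, scanner, kernel, cfg)
        pet_m = reconstruct_pet(s.em, s.mlacf_mu[mode], scanner, kernel, cfg)
        pet_d = reconstruct_pet(s.em, s.dl_mu[mode], scanner, kernel, cfg)
        for tag, pet in (("mlacf", pet_m), ("dl", pet_d)):
            for voi in ("fat", "water", "bone"):
                m = masks[voi]
                if m.n_voxels == 0:
                    continue
                acc[tag][voi].append(
                    rmae(pet, pet_ref, m, np.finfo(float).tiny))
            peak = np.unravel_index(np.argmax(pet_ref.values), pet_ref.shape)
            lesion = isocontour_lesion(pet_ref, peak)
            ref_mean = pet_ref.values[lesion.mask].mean()
            got_mean = pet.values[lesion.mask].mean()
            suv_err[tag].append(100.0 * abs(got_mean - ref_mean) / ref_mean)
    out = {tag: {voi: float(np.mean(v)) for voi, v in vois.items() if v}
           for tag, vois in acc.items()}
    out["suv_lesion_abs_err_pct"] = {tag: float(np.mean(v))
                                     for tag, v in suv_err.items()}
    return out
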