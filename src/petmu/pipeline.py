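"""Run configuration and the end-to-end pipeline.

The pipeline emulates the full study on synthetic subjects:

    phantom -> LSO-TX simulation (pre- and/or post-injection) -> MLTR at
    307/202 keV -> energy mapping + fusion -> TOF emission simulation ->
    MLACF joint reconstruction -> learned enhancement -> PET reconstruction
    with each candidate mu-map -> VOI evaluation report.

The ground-truth mu-map plays the role the CT-derived mu-map plays for
patient data: it is both the enhancement target and the evaluation
reference. Every stage draws randomness from a named substream of the one
global seed, so a run is exactly reproducible from (config, seed).
"""

from __future__ import annotations

import json
import os
from typing import Dict, Literal, Optional, Tuple

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict

from .core import ConfigurationError, VoxelVolume, substream
from .enhance import UNetEnhancer
from .evaluate import (VoiMask, body_mask, build_report,
                       isocontour_lesion, segment_tissues)
from .mu_sources import fuse_tx_mu, map_energy
from .phantom import (Phantom, body_phantom_spec, build_phantom,
                      default_tissue_table)
from .projector import attenuation_factors
from .recon import (MlacfConfig, MltrConfig, OsemConfig, mlacf, mltr,
                    osem_tof)
from .scanner import ScannerModel, TofKernel
from .simulate import (simulate_emission, simulate_transmission,
                       tx_contamination_mean)


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ScannerSection(_Strict):
    n_angles: Optional[int] = None   # default: matched to the grid
    n_radial: Optional[int] = None
    fov_mm: Optional[float] = None
    tof_fwhm_ps: float = 225.0
    tof_bin_width_mm: float = 30.0


class PhantomSection(_Strict):
    shape: Tuple[int, int] = (64, 64)
    voxel_size_mm: float = 1.65
    n_subjects: int = 5
    n_train: int = 4
    n_lesions: int = 1


class SimulationSection(_Strict):
    tx_duration_s: float = 300.0      # 5-minute transmission scan
    em_duration_s: float = 600.0      # 10-minute emission frame
    scatter_fraction: float = 0.1
    randoms_rate: float = 0.002
    contamination_frac: float = 0.05  # tracer leakage into post-injection TX
    tx_mode: Literal["pre", "post", "both"] = "post"
    noiseless: bool = False


class MuSourcesSection(_Strict):
    fuse_fwhm_mm: float = 4.0


class MltrSection(_Strict):
    iterations: int = 8
    subsets: int = 3


class OsemSection(_Strict):
    iterations: int = 4
    subsets: int = 5
    psf_fwhm_mm: float = 0.0
    postfilter_fwhm_mm: float = 2.0


class MlacfSection(_Strict):
    global_iterations: int = 20
    warmup_passes: int = 10
    extract_beta: float = 0.1


class ReconSection(_Strict):
    mltr: MltrSection = MltrSection()
    osem: OsemSection = OsemSection()
    mlacf: MlacfSection = MlacfSection()


class EnhanceSection(_Strict):
    levels: int = 3
    base_channels: int = 8
    patch_size: int = 64
    epochs: int = 40
    batch_size: int = 4
    patches_per_volume: int = 4
    lr: float = 1e-3
    loss: str = "mae"
    augment_scale: float = 0.2
    augment_rotation_deg: float = 10.0


class EvaluateSection(_Strict):
    ref_floor_frac: float = 0.5
    injected_dose_bq: float = 2.0e8
    body_weight_g: float = 7.0e4


class RunConfig(_Strict):
    seed: int = 0
    outdir: Optional[str] = None
    scanner: ScannerSection = ScannerSection()
    phantom: PhantomSection = PhantomSection()
    simulation: SimulationSection = SimulationSection()
    mu_sources: MuSourcesSection = MuSourcesSection()
    recon: ReconSection = ReconSection()
    enhance: EnhanceSection = EnhanceSection()
    evaluate: EvaluateSection = EvaluateSection()


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig(**data)


def _build_scanner(cfg: RunConfig) -> ScannerModel:
    kw = {}
    if cfg.scanner.n_angles:
        kw["n_angles"] = cfg.scanner.n_angles
    if cfg.scanner.n_radial:
        kw["n_radial"] = cfg.scanner.n_radial
    if cfg.scanner.fov_mm:
        kw["fov_mm"] = cfg.scanner.fov_mm
    kw["tof_fwhm_ps"] = cfg.scanner.tof_fwhm_ps
    return ScannerModel.for_grid(cfg.phantom.shape,
                                 cfg.phantom.voxel_size_mm, **kw)


TX_WINDOWS = {307.0: (275.0, 355.0), 202.0: (165.0, 247.0)}


def tx_mu_map(phantom: Phantom, scanner: ScannerModel, cfg: RunConfig,
              seed: int, post_injection: bool) -> VoxelVolume:
    """LSO-TX mu-map: MLTR per window, energy mapping, fusion + smoothing."""
    sim = cfg.simulation
    mapped = []
    for energy in (307.0, 202.0):
        window = TX_WINDOWS[energy]
        contam = None
        if post_injection and sim.contamination_frac > 0:
            contam = tx_contamination_mean(
                phantom.activity, scanner, window, sim.tx_duration_s,
                sim.contamination_frac)
        counts, blank = simulate_transmission(
            phantom.mu(energy), scanner, window, sim.tx_duration_s,
            seed=seed, noiseless=sim.noiseless, contamination=contam)
        mu_e = mltr(counts, blank, scanner,
                    MltrConfig(iterations=cfg.recon.mltr.iterations,
                               subsets=cfg.recon.mltr.subsets),
                    grid_shape=tuple(cfg.phantom.shape),
                    voxel_size_mm=cfg.phantom.voxel_size_mm)
        mapped.append(map_energy(mu_e))
    return fuse_tx_mu(mapped[0], mapped[1], cfg.mu_sources.fuse_fwhm_mm)


def mlacf_mu_map(phantom: Phantom, scanner: ScannerModel, kernel: TofKernel,
                 cfg: RunConfig, seed: int, init_mu: VoxelVolume):
    """TOF emission simulation + MLACF seeded by the transmission mu-map."""
    sim = cfg.simulation
    em = simulate_emission(phantom.activity, phantom.mu(511), scanner, kernel,
                           sim.em_duration_s, sim.scatter_fraction,
                           sim.randoms_rate, seed=seed,
                           noiseless=sim.noiseless)
    from .recon import AcfToMuConfig

    mcfg = MlacfConfig(
        global_iterations=cfg.recon.mlacf.global_iterations,
        warmup_passes=cfg.recon.mlacf.warmup_passes,
        extract=AcfToMuConfig(beta=cfg.recon.mlacf.extract_beta))
    result = mlacf(em.counts, em.additive, scanner, kernel, init_mu, mcfg,
                   track_loglik=False)
    return result, em


def reconstruct_pet(em, mu_map: VoxelVolume, scanner: ScannerModel,
                    kernel: TofKernel, cfg: RunConfig) -> VoxelVolume:
    acf = attenuation_factors(mu_map, scanner)
    o = cfg.recon.osem
    return osem_tof(em.counts, acf, em.additive, scanner, kernel,
                    OsemConfig(iterations=o.iterations, subsets=o.subsets,
                               psf_fwhm_mm=o.psf_fwhm_mm,
                               postfilter_fwhm_mm=o.postfilter_fwhm_mm),
                    grid_shape=tuple(cfg.phantom.shape),
                    voxel_size_mm=cfg.phantom.voxel_size_mm)


def _enhancer(cfg: RunConfig, seed: int) -> UNetEnhancer:
    e = cfg.enhance
    return UNetEnhancer(levels=e.levels, base_channels=e.base_channels,
                        patch_size=e.patch_size, ndim=2, loss=e.loss,
                        lr=e.lr, epochs=e.epochs, batch_size=e.batch_size,
                        patches_per_volume=e.patches_per_volume,
                        augment_scale=e.augment_scale,
                        augment_rotation_deg=e.augment_rotation_deg,
                        seed=seed)


def run_pipeline(cfg: RunConfig, outdir: Optional[str] = None) -> Dict:
    """Execute the full synthetic study; returns a results dictionary.

    When an output directory is given (argument or config), all volumes are
    persisted as NIfTI, the report as TSV + JSON, and the resolved config as
    YAML.
    """
    outdir = outdir or cfg.outdir
    ph_cfg = cfg.phantom
    if ph_cfg.n_train >= ph_cfg.n_subjects:
        raise ConfigurationError("n_train must be < n_subjects")
    scanner = _build_scanner(cfg)
    kernel = TofKernel.for_scanner(scanner, cfg.scanner.tof_bin_width_mm)
    table = default_tissue_table()
    modes = {"pre": [False], "post": [True], "both": [False, True]}[
        cfg.simulation.tx_mode]
    mode_name = {False: "pre", True: "post"}
    primary_mode = mode_name[modes[-1]]

    subjects = []
    for s in range(ph_cfg.n_subjects):
        sub_seed = int(substream(cfg.seed, "subject", s).integers(2 ** 31))
        spec = body_phantom_spec(tuple(ph_cfg.shape), seed=sub_seed,
                                 n_lesions=ph_cfg.n_lesions,
                                 voxel_size_mm=ph_cfg.voxel_size_mm)
        phantom = build_phantom(spec, table)
        entry = {"id": s, "phantom": phantom, "mlacf_mu": {}, "em": None}
        for post in modes:
            mu_tx = tx_mu_map(phantom, scanner, cfg, sub_seed, post)
            result, em = mlacf_mu_map(phantom, scanner, kernel, cfg,
                                      sub_seed, mu_tx)
            entry["mlacf_mu"][mode_name[post]] = result.mu_map
            entry["em"] = em
        subjects.append(entry)

    train = subjects[:ph_cfg.n_train]
    test = subjects[ph_cfg.n_train:]
    est = _enhancer(cfg, seed=int(substream(cfg.seed, "train").integers(2 ** 31)))
    est.fit([s["mlacf_mu"][primary_mode] for s in train],
            [s["phantom"].mu(511) for s in train])

    ev = cfg.evaluate
    reports = []
    for s in test:
        phantom = s["phantom"]
        truth = phantom.mu(511)
        mu_mlacf = s["mlacf_mu"][primary_mode]
        mu_dl = est.predict(mu_mlacf)
        s["dl_mu"] = mu_dl
        masks = segment_tissues(truth)
        masks["body"] = VoiMask(body_mask(truth, erode=1), "body")
        mu_report = build_report(
            {"reference": truth, "mlacf": mu_mlacf, "dl_mlacf": mu_dl},
            "reference", masks, ev.ref_floor_frac)

        pets = {}
        for tag, mu in (("reference", truth), ("mlacf", mu_mlacf),
                        ("dl_mlacf", mu_dl)):
            pets[tag] = reconstruct_pet(s["em"], mu, scanner, kernel, cfg)
        act_masks = dict(masks)
        if phantom.activity.values.max() > 0:
            peak = np.unravel_index(np.argmax(pets["reference"].values),
                                    pets["reference"].shape)
            act_masks["lesion"] = isocontour_lesion(pets["reference"], peak)
        pet_report = build_report(pets, "reference", act_masks,
                                  ev.ref_floor_frac,
                                  suv_params=(ev.injected_dose_bq,
                                              ev.body_weight_g))
        s["pets"] = pets
        mu_report.table.insert(0, "kind", "mu_map")
        pet_report.table.insert(0, "kind", "pet")
        for rep in (mu_report, pet_report):
            rep.table.insert(0, "subject", s["id"])
        reports.append((s["id"], mu_report, pet_report))

    import pandas as pd

    full = pd.concat([r.table for _, mu_r, pet_r in reports
                      for r in (mu_r, pet_r)], ignore_index=True)
    results = {
        "config": cfg.model_dump(),
        "scanner": scanner,
        "report": full,
        "subjects": subjects,
        "estimator": est,
    }

    if outdir:
        os.makedirs(outdir, exist_ok=True)
        from .io import write_volume

        full.to_csv(os.path.join(outdir, "report.tsv"), sep="\t",
                    index=False, float_format="%.6g")
        with open(os.path.join(outdir, "report_meta.json"), "w") as fh:
            json.dump({"seed": cfg.seed, "config": cfg.model_dump()}, fh,
                      indent=2, default=str)
        with open(os.path.join(outdir, "config_resolved.yaml"), "w") as fh:
            yaml.safe_dump(cfg.model_dump(), fh)
        for s in test:
            sid = s["id"]
            write_volume(s["phantom"].mu(511),
                         os.path.join(outdir, f"sub{sid}_mu_ref.nii.gz"))
            write_volume(s["mlacf_mu"][primary_mode],
                         os.path.join(outdir, f"sub{sid}_mu_mlacf.nii.gz"))
            write_volume(s["dl_mu"],
                         os.path.join(outdir, f"sub{sid}_mu_dl.nii.gz"))
            for tag, pet in s["pets"].items():
                write_volume(pet,
                             os.path.join(outdir, f"sub{sid}_pet_{tag}.nii.gz"))
    return results
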