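# petmu — CT-free PET attenuation correction from LSO background radiation

Attenuation correction is the step in PET image formation that compensates
for annihilation photons absorbed or scattered inside the body. Clinically
it relies on a CT scan converted to a 511 keV attenuation map (µ-map), which
adds radiation dose and can be misregistered with the PET data. Long
axial field-of-view PET scanners are sensitive enough to detect the
intrinsic radiation of their own lutetium-based (LSO) scintillators —
Lu-176 decays emit gammas at 307, 202 and 88 keV — turning the detector
itself into a transmission source. `petmu` implements and evaluates, on
synthetic phantom cohorts, a CT-free pipeline that turns this LSO
transmission (LSO-TX) signal plus the time-of-flight (TOF) emission data
into quantitative µ-maps:

1. **LSO-TX simulation and MLTR.** Counts in two energy windows
   (275–355 keV and 165–247 keV) follow the Poisson transmission model
   `ȳᵢ = bᵢ exp(−(Pµ)ᵢ)` with blank rate `bᵢ` per line of response. Each
   window is reconstructed by maximum-likelihood transmission tomography
   (MLTR, separable-paraboloid ordered-subsets update; 8 iterations,
   3 subsets), mapped to 511 keV with a two-segment (soft-tissue/bone)
   scaling, averaged, and smoothed with a 4 mm FWHM Gaussian.
2. **MLACF joint reconstruction.** With the TOF emission sinogram
   `yᵢₜ ~ Poisson(aᵢ (Pλ)ᵢₜ + sᵢₜ + rᵢₜ)` the activity λ and the per-LOR
   attenuation factors `aᵢ = exp(−∫µ dl)` are estimated jointly: TOF-OSEM
   activity updates alternate with the closed-form per-LOR maximum-likelihood
   factor update `âᵢ = (Σₜ yᵢₜ − Σₜ sᵢₜ)/Σₜ (Pλ)ᵢₜ` over 20 global
   iterations. The inherent global scale ambiguity of the factored mean
   is anchored against the LSO-TX µ-map; a penalised weighted least-squares
   inversion of `−ln âᵢ` yields the MLACF µ-map.
3. **Learned enhancement.** A patch-based convolutional encoder-decoder
   (U-Net with PReLU activations, z-score input normalisation, geometric
   ±20 % zoom / ±10° rotation augmentation) is trained with k-fold
   cross-validation to map MLACF µ-maps to the reference µ-maps, sharply
   reducing their noise and artefacts.
4. **Evaluation.** PET images are reconstructed with TOF-OSEM (4 iterations,
   5 subsets, 2 mm post-filter) using each candidate µ-map, and µ-maps/PET
   images are compared with `rME(%) = 100·mean[(Iₓ−I_ref)/I_ref]` and
   `rMAE(%) = 100·mean[|Iₓ−I_ref|/I_ref]` over threshold-segmented VOIs
   (fat 0.080–0.090, water-based soft tissue 0.090–0.105, bone
   > 0.105 cm⁻¹ with marrow hole-filling), 50 %-of-max lesion isocontours,
   and standardised uptake values (SUV).

Everything runs on synthetic, analytically-defined body phantoms whose
ground-truth µ-map plays the role the CT-based µ-map plays for patients; no
external data are needed. The package is aimed at researchers in PET
reconstruction and attenuation-correction methodology who want a desk-scale,
fully reproducible testbed for joint-estimation and learned-enhancement
ideas.

## Worked example

Run the end-to-end pipeline on five synthetic subjects (four used to train
the enhancement network, one held out for testing):

```python
from petmu.pipeline import RunConfig, run_pipeline

cfg = RunConfig(**{
    "seed": 7,
    "phantom": {"shape": (64, 64), "n_subjects": 5, "n_train": 4},
    "enhance": {"levels": 3, "base_channels": 8, "epochs": 30,
                "patches_per_volume": 4, "batch_size": 4},
})
report = run_pipeline(cfg)["report"]
print(report[report.kind == "mu_map"].to_string(index=False))
```

which prints (µ-map errors of the held-out subject against its ground
truth):

```
 subject   kind    image   voi  n_voxels    rme_pct  rmae_pct
       4 mu_map    mlacf   fat       428 -40.256359 41.886678
       4 mu_map    mlacf water      1044 -10.975792 15.817171
       4 mu_map    mlacf  bone       112  -6.848292  9.360489
       4 mu_map    mlacf  body      1338 -11.976422 16.468072
       4 mu_map dl_mlacf   fat       428  -8.320176 15.344609
       4 mu_map dl_mlacf water      1044  -1.436922  8.277120
       4 mu_map dl_mlacf  bone       112  -3.540963  9.183637
       4 mu_map dl_mlacf  body      1338   0.500542  7.475434
```

The MLACF µ-map is noisy (16.5 % body rMAE); the learned enhancement more
than halves the error (7.5 %). The same report contains the PET rows: PET
reconstructed with the enhanced µ-map reaches ~1.7 % body rMAE against the
reference reconstruction (vs ~4.9 % for the raw MLACF µ-map) and ~1.7 %
absolute SUV error in the lesion isocontour VOI.

The same stages are available as a CLI (`petmu phantom`, `petmu simulate`,
`petmu recon-mltr`, `petmu recon-mlacf`, `petmu recon-pet`,
`petmu enhance-train`, `petmu enhance-apply`, `petmu crossval`,
`petmu evaluate`, `petmu run`), with volumes stored as NIfTI and sinograms
as HDF5.

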