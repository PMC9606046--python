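# Methods

This note documents the models implemented in `petmu`, the parameters that
matter, what the synthetic data do and do not emulate, and the numerical
choices made where the design was open.

## Scanner model and geometry

The scanner is an idealised parallel-beam TOF-PET system. The projector is
ray-driven with bilinear interpolation: each line of response (LOR) is
sampled at steps of one voxel, and the gather is materialised as a sparse
matrix per (geometry, angle-subset), so the back-projector is the exact
matrix transpose and `⟨Px, y⟩ = ⟨x, Pᵀy⟩` holds to rounding. 3-D volumes are
projected slice-by-slice; parallel-beam physics is separable in z, and the
phantom study runs in 2-D (one transaxial slice) by default for desk-scale
speed — all operations accept 3-D grids.

TOF is modelled by a Gaussian kernel over discrete TOF bins. For a timing
resolution Δt (FWHM, default 225 ps) the spatial localisation FWHM is
`c·Δt/2` ≈ 34 mm; the kernel is truncated at 3σ and renormalised per source
position, which makes the TOF sinogram marginalise exactly onto the non-TOF
projection (the normalisation contract the tests assert). Default TOF bin
width is 30 mm with enough bins to cover the field-of-view diagonal.

Acquisition constants follow the simulated protocol: open 160–725 keV
energy window, 6.64 ns coincidence window, LSO-TX energy windows 275–355 keV
(307 keV line) and 165–247 keV (202 keV line), 1.65 mm isotropic voxels,
5-minute transmission and 10-minute emission frames.

The LSO-TX blank rates (1.4 and 0.9 counts/s per LOR for the 307 and
202 keV windows) are simulation settings chosen once so that a 5-minute
scan yields MLTR reconstructions that are visibly noisy but convergent
(tens of transmitted counts per body-crossing LOR); they are not claims
about any physical scanner, whose crystal-level source distribution we do
not model. Likewise the emission sensitivity (2·10⁻⁴ counts per
Bq/mL·cm per second per LOR) sets a realistic count level (~10⁷ counts per
frame at the default phantom activities).

## Phantoms and tissue table

Phantoms are painter's-order compositions of ellipses and boxes: a fat
outline, water-based soft-tissue interior, two lungs, a spine (cortical
bone shell around marrow) and hot lesions; a per-subject seed jitters
positions and semi-axes to give a cohort anatomical variability. Ground
truth is analytic — every voxel carries its tissue's linear attenuation
coefficient (LAC) at 88/202/307/511 keV and an activity concentration.

LACs derive from published photon mass-attenuation tables by log-log
interpolation (`scripts/derive_tissue_lacs.py` regenerates them): water at
ρ=1 for soft tissue, water at ρ=0.3 for inflated lung, the cortical-bone
spectrum at an effective ρ=1.6 for bone, and water-shaped spectra scaled to
0.086 / 0.098 cm⁻¹ at 511 keV for fat and marrow (both Compton-dominated).
At 511 keV these land inside the evaluation thresholds (fat
0.080–0.090, water 0.090–0.105, bone > 0.105 cm⁻¹) so threshold
segmentation of the true µ-map recovers the generating labels exactly —
a property the tests assert.

What the generator does **not** emulate: anatomical realism (organs,
XCAT-style anatomy), motion, positron range, detector normalisation/dead
time, crystal-level LSO source geometry, and scatter estimation (scatter is
simulated as a smooth TOF-uniform background and handed to the
reconstructors as a *known* additive term). Passing tests therefore show
algorithmic correctness and directional behaviour at desk scale, not
clinical performance.

## MLTR

Transmission model `ȳᵢ = bᵢ exp(−(Pµ)ᵢ)`. The update is the
separable-paraboloid (convex) ordered-subsets step

    µ ← [µ + Pᵀ(ȳ − y) / Pᵀ((P1)·ȳ)]₊

monotone in the one-subset limit; defaults are 8 iterations with 3
interleaved angle subsets. Rays crossing no voxels keep their value
(zero-curvature guard).

## Energy mapping and fusion

Window µ-maps are mapped to 511 keV with a continuous two-segment
multiplicative model split at a LAC breakpoint: below it the soft-tissue
scale (water LAC ratio), above it a bone slope chosen so water and bone map
exactly. A single global scale would be wrong at the lower energies because
of bone's photoelectric contribution. Breakpoint defaults are per energy —
0.18 cm⁻¹ at 202 keV and 0.15 cm⁻¹ at 307 keV — because bone's LAC at
307 keV (≈0.176 cm⁻¹) sits *below* 0.18, which would otherwise leave the
bone segment unreachable. Mapping is applied per window before the
unweighted average (weights configurable), followed by a 4 mm FWHM Gaussian
(σ = FWHM/2.3548).

The bilinear HU→LAC conversion uses the standard piecewise-linear form with
its breakpoint at water (0 HU → 0.096 cm⁻¹), the air anchor (−1000 HU → 0)
fixing the lower slope and 5.1·10⁻⁵ cm⁻¹/HU above; all coefficients live in
`BilinearParams`.

## MLACF

Per global iteration (20 by default): one TOF-OSEM pass for the activity
with the current factors; the closed-form per-LOR ML factor
`âᵢ = (Σₜyᵢₜ − Σₜsᵢₜ)/Σₜ(Pλ)ᵢₜ` clipped to [10⁻³, 1]; and scale anchoring.
The factored mean `aᵢ(Pλ)ᵢₜ` is invariant under `(λc, a/c)`, so one global
scalar is applied to the factors (inverse to the activity), chosen so the
mean log-factor over a body mask (LORs with `a_init < 0.98·max`) matches
the LSO-TX prediction. Numerical choices that matter:

* **Warm-up.** Ten OSEM passes with the transmission-derived factors run
  before the first factor update. A factor step against a barely-converged
  activity corrupts low-signal LORs, and the corruption feeds back through
  the sensitivity image; warm-up removes this transient.
* **Low-signal LORs.** LORs whose unattenuated projection is below 10⁻³ of
  the maximum retain the initialisation-derived factor: the ML factor
  estimate's variance scales like 1/(Pλ), so the likelihood carries
  essentially no information there and the transmission prior is the right
  fallback. These LORs are also excluded from the anchoring mask.
* **µ extraction.** The factor sinogram is inverted to a µ-map by penalised
  weighted least squares on `pᵢ = −ln âᵢ` (conjugate gradients, 100
  iterations, started from the LSO-TX map, clamped at zero). Weights are the
  trues counts `Σₜyᵢₜ − Σₜsᵢₜ`, the inverse-variance weighting for Poisson
  factor noise. The smoothness weight β is 10⁻³ for clean factors (the
  value used when inverting noiseless, exact factors) and 0.1 inside the
  MLACF pipeline, where per-LOR factors carry ~5–10 % Poisson noise at the
  simulated count levels. The resulting MLACF µ-maps have 10–20 % body
  rMAE — noisy and artefacted, which is exactly the input regime the
  enhancement network is meant for.

The alternating structure (activity first, one inner pass, TOF-summed
factor statistics) is one reasonable instantiation of the joint-estimation
family; inner iteration counts and factor smoothing in vendor prototypes
are unpublished, so these choices are documented here rather than claimed
canonical.

## TOF-OSEM

Multiplicative update `λ ← λ·Pᵀ[a·y/ȳ]/Pᵀ[a]` with `ȳ = a(Pλ) + s`,
interleaved angle subsets, optional image-space Gaussian PSF inside the
system model (transpose-symmetric, default off) and a 2 mm FWHM Gaussian
post-filter; PET defaults are 4 iterations and 5 subsets. With one subset
the loop reduces bit-for-bit to MLEM (asserted against a hand-rolled MLEM
in the tests). Reconstructed activity carries the `duration × sensitivity`
scale; all reported metrics are relative, so the scale cancels.

## Enhancement network

A compact N-dimensional U-Net implemented in numpy with manual
backpropagation (3^d same convolutions, channel-wise PReLU, 2× average
pooling, nearest upsampling, skip concatenation) plus a global residual
connection — the network predicts a correction to its input, the natural
parameterisation for µ-map enhancement. Training: per-volume z-score
normalisation (the paired target shares the input volume's statistics so
predictions can be inverted with stats available at inference), random
64-per-axis patches drawn preferentially from the body (≥ 50 % non-air),
shared geometric augmentation (±20 % zoom, ±10° rotation — geometric
resampling, not intensity scaling), mean-absolute-error loss, Adam at
10⁻³. Everything is deterministic given the seed. Full-volume prediction
tiles with half-patch stride and Hann blending, then denormalises and
clamps at zero.

The architecture default is five levels with 64-per-axis patches (2-D uses
64×64); the desk-scale cross-validation study uses a reduced network
(3 levels, 8 base channels, 30 epochs, ~1 minute of CPU training per fold)
— enough capacity to denoise the 64×64 MLACF maps, small enough to keep
the whole 5-fold study in minutes. Loss, optimiser and epoch count are
surfaced in `TrainConfig`; the defaults are pragmatic choices, not tuned
optima.

## Cohort study and evaluation

The study (`petmu.study`) generates 20 phantoms, runs the full
transmission→MLACF chain per subject (pre- and post-injection transmission;
post-injection adds a contamination term proportional to the body-activity
line integral, peaking at 5 % of blank counts — an explicit stand-in for
tracer leakage into the transmission windows), and cross-validates the
enhancement with 5 as-equal-as-possible disjoint folds. Each subject's
cross-validated prediction comes from the one fold in which it is a test
subject; the same fold model is applied to that subject's pre-injection
MLACF map for the pre/post comparison (a single shared model isolates the
transmission-data difference).

Metrics follow the voxelwise definitions: rME and rMAE are computed per
voxel then averaged over the VOI, with a reference floor (half the VOI
median for µ-maps; positive reference for PET) guarding against division
blow-ups. Bone segmentation is threshold + per-component hole filling (so
marrow joins bone); the fat range is half-open at 0.090 cm⁻¹ to keep
fat/water disjoint. Lesion VOIs are 50 %-of-maximum isocontours around the
local maximum reached by hill-climbing from the seed. SUV divides the
activity concentration by dose/weight (1 g/mL tissue density).

At these conditions (seed 1) the study measures: MLACF body rMAE ~17 %,
enhanced ~7 %, every fold improved, median fold improvement factor ~2.7;
per-tissue enhanced µ-map rMAE fat ~16 %, water ~7 %, bone ~10 %;
pre/post enhanced-map body-rMAE difference ~0.9 percentage points; PET
rMAE improvement factors ~2–2.9 across tissues and lesion-SUV error ~2 %.
These are scaled-down directional analogues — the absolute numbers depend
on the synthetic count levels and 2-D geometry and are not comparable to
patient-cohort values.

## Known limitations

* Parallel-beam geometry; no cylindrical-scanner effects, arc correction or
  axial obliques.
* Scatter and randoms are known additive terms; estimating them is out of
  scope.
* The MLACF variant is one member of the family; no voxel-space attenuation
  update (MLAA) is provided.
* 2-D default; 3-D paths are implemented and tested for correctness but are
  slow for large grids in pure numpy.
* The contamination model for post-injection transmission is phenomenological
  and configurable, not a physical coincidence-leakage simulation.
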