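# Methods

This note documents the models, conventions, and design choices behind
`perfsynth`: what each component assumes, which parameters matter and why
they default to what they do, and what the bundled phantom simulator does
and does not emulate.

## The synthesis problem

The package learns four mappings from non-contrast head CT (NCCT, in
Hounsfield units) to CT perfusion parametric maps: CBF (mL/100g/min), CBV
(mL/100g), MTT (s), TTP (s). The input to every prediction is a 3-channel
pseudo-RGB image: the target axial slice with its neighbours at a fixed
vertical offset (default 4 mm), which supplies the through-plane context a
single slice lacks. Outputs live in normalized [0, 1] map space defined by
fixed physiological ranges — CBF [0, 60], CBV [0, 4], MTT [0, 12],
TTP [0, 25] — and are converted back to physical units at inference.

## Preprocessing conventions

Pipeline order: HU windowing (center 40, width 80) → skull stripping →
resizing to 256×256 → pseudo-RGB stacking → map normalization → static
augmentation → z-score standardization at the network input boundary.
Windowing before stripping makes the bone threshold scanner-independent
(bone always saturates the brain window); augmentation operates on
normalized data so the out-of-frame fill value 0 remains meaningful.

Skull stripping is a threshold-plus-morphology baseline: pixels strictly
inside the open interval of the display window are candidates (background
air windows to 0, bone to 1), speckle is removed by a binary opening, the
largest connected component is kept, and interior holes (ventricles) are
filled. This is adequate for phantom data and for clean clinical slices;
it is not a learned brain extractor and will fail on slices dominated by
artifact. An empty mask raises an error in preprocessing (the case is
excluded) but is tolerated during whole-volume inference, where such
slices simply produce zero maps.

Static augmentation draws one rigid transform per emitted copy — a
horizontal flip with probability 0.5, a rotation uniform in ±10°, and
integer translations uniform in ±30 px per axis — and applies the *same*
transform to all seven channels and the mask (bilinear for intensities,
nearest for masks, rotations about the image center). The ±30 px default
is calibrated to 256 px inputs; scaled-down runs should scale it
proportionally, as the tests do.

Two normalizations coexist deliberately: the physical→[0, 1] map
normalization is the stored representation, while zero-mean/unit-sd
standardization with training-pool statistics is applied only at the
generator's input boundary (and the statistics are persisted in
checkpoints). The discriminators and all losses operate in [0, 1] map
space.

## Network

The generator is a U-Net with one shared trunk and four task branches.
Eight stride-2 4×4 convolution stages halve 256 px down to a 1×1
bottleneck; channel widths follow the doubling ladder 64→512 capped at
512. The first four stages are shared across the four map tasks; each task
owns the remaining four encoder stages (so each branch has its own
1×1×512 bottleneck), eight skip-connected transposed-convolution decoder
stages (LeakyReLU 0.2 throughout, Tanh at the branch output, affinely
mapped to [0, 1]), and a PILO output layer. The PILO layer is a 1×1
transposed convolution over the 4-channel concatenation of the decoded
perfusion channel with the three NCCT channels; its input-channel weights
can be rescaled at inference (`pilo_rescale(alpha_perf, alpha_anat)`) to
trade hemodynamic against anatomical content, with (1, 1) the identity.
PILO weights are trained jointly with the rest of the generator and
initialized near the identity on the perfusion channel.

Each of the four discriminators is a 70×70 PatchGAN on the 4-channel
(NCCT, map) pair: five 4×4 stages with strides (2, 2, 2, 1, 1) and widths
(64, 128, 256, 512, 1), sigmoid patch output (30×30 at 256 px input). The
patch targets are all-ones for real pairs and all-zeros for synthesized
pairs.

**Parameter ledger.** Every convolution and transposed convolution carries
a bias; normalization layers carry no learnable affine parameters. Under
this ledger the default configuration counts to exactly 209,352,408
generator parameters (shared trunk 2,756,544 + 4 × 51,648,966 per branch,
of which 5 are the PILO layer) and 4 × 2,765,761 = 11,063,044
discriminator parameters. `parameter_report` exposes the per-block
breakdown; the block counts sum to the totals.

Normalization is batch normalization when the batch size exceeds one and
instance normalization otherwise. Batch statistics are used at inference
as well as in training — the usual practice for image-translation GANs,
where running averages collected under an adversarial schedule are
unreliable; running statistics are still tracked and checkpointed for
diagnostics. The first encoder stage, each branch bottleneck, and the
final decoder stage carry no normalization. Weights initialize from a
zero-mean Gaussian with sd 0.02, seeded.

## Objective

Four terms, combined as `L_GAN + λ1·L_L1 + λ2·L_EXT + λ3·L_MML`:

* **Adversarial.** Patchwise binary cross-entropy averaged over the four
  map kinds (a 1/N prefactor with N = 4). The generator side uses the
  non-saturating `−log D(fake)` form by default (a config flag restores
  the saturating form); probabilities are clamped at `eps = 1e-7`.
* **L1.** Mean absolute difference in [0, 1] map space, averaged over
  pixels then map kinds.
* **Extrema.** The real map is min–max normalized per image to
  [−0.5, 0.5] and squared to form a weight map in [0, 0.25] — zero at the
  midpoint, maximal at the extremes — which multiplies the squared
  difference of the min–max-normalized generated and real maps.
  Min–max statistics are computed per slice within the brain mask, never
  across the batch. A constant map has no extremes: its weight map is
  identically zero (logged). This term concentrates training signal on
  the hypo-/hyper-perfused regions that carry the diagnosis.
* **Multimodal.** `mean |G_CBF(x) ⊙ G_MTT(x) − CBV|`, the central volume
  principle applied *literally in normalized map space*. Note the
  dimensional subtlety: with the canonical ranges the physical identity
  CBV = CBF × MTT/60 implies `cbv_n = 3 · cbf_n · mtt_n` for the
  normalized quantities, so the literal product form is not the exact
  normalized identity. The loss is kept in the literal form; an optional
  `consistency_factor` (default 1, i.e. off) exposes the ×3 correction
  for experimentation. The phantom, by contrast, enforces the identity in
  physical units exactly.

λ values: λ1 = 100 follows the standard image-translation convention for
the L1 term; λ2 = 100 and λ3 = 10 put the extrema and multimodal terms on
comparable magnitude on phantom batches at initialization (extrema values
are ~100× smaller than L1 because of the ≤0.25 weight and squared error;
the multimodal residual is ~10× the L1 at initialization). All three are
config fields and are recorded in the training log.

## Training

Per iteration: (1) the four discriminators update on one real and one
generated (detached) pair per sample, minimizing the patch BCE averaged
over map kinds; (2) the discriminators are frozen and the generator
updates on the full objective. Adam with β1 = 0.5, β2 = 0.999 and a
constant learning rate 1e-4 for both networks; no decay. Batch size 8 and
50 epochs are the full-scale defaults. The validation split (default 100
slices) is sampled at the image level from the provided pool with the
global seed, and the generator loss is recorded once per epoch.
`validate()` without discriminators reports the λ-weighted non-adversarial
part (L1 + extrema + multimodal) — the part that is comparable across
epochs without reference to a co-evolving discriminator; passing the
discriminators adds the adversarial term. A non-finite loss aborts with a
diagnostic dump. Everything — data order, augmentation, initialization,
updates — is deterministic given the config seed on a fixed machine.

Whole-volume inference produces one 4-map prediction per axial position
with both ±offset neighbours (a 161-slice, 1 mm volume with a 4 mm offset
yields 153 positions); boundary slices are skipped and reported, outputs
are denormalized to physical units and masked to the brain.

The networks run on a small reverse-mode autodiff engine written on NumPy
(`_autodiff.py`: tensors, elementwise ops, reductions with min/max
subgradients, im2col-based 2-D convolution and its transpose). Gradients
are validated against central finite differences in the test-suite, and
the convolution forward against an explicit loop reference.

**Scaled test configuration.** The repository's test surface trains a
width/resolution-scaled model — 64×64 inputs with base width 16 for the
learning smoke test (200 slices, 5 epochs), and 32×32 with base width 8
for the multi-seed physiology-loss ablation (60 slices, 4 epochs, 5 paired
seeds) — so the full loop runs on one CPU core in minutes. Full-scale
settings remain the configuration defaults. The ablation checks a
directional property: the median held-out central-volume residual
`|ĈBF·M̂TT − CBV|` is lower with λ3 > 0 than with λ3 = 0 under otherwise
identical seeds. Absolute image-quality numbers from full-scale training
on clinical cohorts are not reproducible at this scale and are not
asserted.

## Phantom simulator

`perfsynth.phantom` generates paired NCCT + perfusion volumes with the
statistical structure the network and evaluation assume. Geometry: an
elliptical brain inside a high-attenuation skull ring (1000 HU) with a
thin dark subarachnoid rim, an inner white-matter ellipse, two elliptical
CSF ventricles, replicated across slices with a slow axial shrink so the
pseudo-RGB neighbours carry real through-plane signal. Tissue baselines
sit in the interiors of the canonical normalization ranges (gray: 38 HU,
CBF 50, MTT 4 s; white: 28 HU, CBF 22, MTT 4.8 s; CSF near-zero
perfusion) — textbook normal-tissue values, configurable per phantom;
no cohort-specific calibration is implied. Maps are smoothed within the
brain (σ = 2 px) so tissue transitions are gradual, and CBV is *derived*
as CBF × MTT / 60, making the central volume principle exact before noise.

Lesions are concentric ellipses: the penumbra delays TTP by > 6 s
(default 8 s) with preserved CBV and mildly reduced CBF; the core sets
CBF to a fraction < 0.30 (default 0.2) of the mirrored contralateral
value and CBV to a fraction (default 0.45) of its mirror, with MTT
re-derived from the identity (coming out prolonged, as in real ischemia).
The contralateral reference mirrors the slice across the vertical
midline; lesion geometry must stay inside the brain and on one side of
the midline, else generation fails with a geometry error. The NCCT
correlate of the core (`ncct_hypodensity`) defaults to 0, emulating
CT-occult early stroke. Severity labels are computed from the generated
masks with the same mismatch-ratio classifier used for evaluation, so
label consistency holds by construction.

Noise: additive Gaussian on NCCT (default sd 3 HU, typical head-CT noise)
and independent multiplicative log-normal noise on each map (default
log-sd 0.05), which preserves positivity; maps are clipped to their
ranges and zeroed outside the brain. With noise off the central-volume
identity is float-exact; with defaults it holds to within the combined
noise (median relative residual well under 15%).

What the phantom does *not* emulate: real anatomy (gyri, vascular
territories), contrast-bolus kinetics or deconvolution artifacts,
scanner-specific noise texture, beam hardening, motion, or imperfect
NCCT/CTP co-registration. Passing tests on phantoms therefore validate
the pipeline's mechanics, physiological consistency and statistical
behaviour — not clinical image quality on patient data.

## Evaluation

SSIM and UQI are computed in sliding windows over image pairs cropped to
the tight bounding box of the brain mask (background inflates both
metrics). SSIM: 11×11 Gaussian window, σ = 1.5, stabilizers
c1 = (0.01 L)², c2 = (0.03 L)² with dynamic range L = 1 in normalized map
space — the original metric's conventions. UQI: the same statistic with
zero stabilizers over an 8×8 uniform window; degenerate windows (zero
denominator) contribute 1 when the windows agree and 0 otherwise. Both
are windowed rather than global; the choice is recorded in the metric
parameters and every parameter is configurable. PSNR is deliberately
absent: pixelwise intensity comparison misrepresents perceptual and
diagnostic similarity for perfusion maps.

Severity stratification uses the mismatch ratio — core pixels divided by
penumbra pixels summed over the stack, with 0/0 → 0 and positive/0 → +∞
(graded severe). For phantoms the stored truth masks are used; for real
map volumes a threshold surrogate is provided (core: CBF below 30% of the
mirrored contralateral value; penumbra: TTP more than 6 s above the
contralateral median).

## Reader-agreement statistics

The two-trial blinding scaffold assigns each case's real and synthetic
arms to different trials, shuffles each trial independently, and issues
per-trial pseudo-IDs with a persisted unblinding map. Agreement per
question: percent agreement with a Wilson score interval; Cohen's κ with
the Fleiss–Cohen–Everitt delta-method standard error (cross-checked
against `statsmodels`) and a seeded bootstrap alternative (B = 2000). A
degenerate table whose chance agreement is 1 — both arms constant — is
assigned κ = 0 with a (0, 0) interval: with no response variability the
chance-corrected statistic carries no information, which is exactly the
regime where percent agreement and κ diverge.

The κ power analysis is Monte-Carlo: paired responses are simulated from
the joint distribution `(1 − κ)·outer(m, m) + κ·diag(m)`, which has
common marginals `m` in both arms and population κ equal to the target
exactly; each replicate is tested with a two-sided Wald statistic. The
marginals are a required argument — power depends strongly on them and no
silent default would be honest. The construction requires a common
marginal vector; incompatible inputs are rejected.

## Numerical choices and edge cases

* Min–max normalizations are guarded by `eps = 1e-7`; constant images
  normalize to zero rather than dividing by zero.
* Min/max subgradients split equally among tied extremes.
* Discriminator probabilities are clamped to [eps, 1−eps] before logs.
* The mismatch ratio defines 0/0 = 0 and k/0 = +∞ (severe).
* UQI's zero-denominator windows: 1 if means equal and variances zero,
  else 0.
* Severity thresholds are closed on the left at 0.5: ratio = 0.5 is
  mild/moderate, anything above is severe.
* Resizing: bilinear for intensities, nearest for masks, no
  anti-aliasing, identity when already at target size.

## Known limitations

* The skull stripper is a threshold-morphology baseline, not a clinical
  brain extractor.
* The multimodal loss is dimensionally literal (see above); whether the
  ×3 consistency factor helps is an open empirical question exposed as a
  flag.
* Batch-statistic normalization at inference makes batched predictions
  depend (weakly) on batch composition; single-slice inference is exact.
* CPU-only: full-scale (256 px, width 64) training is supported by the
  code but impractical without substantial compute; the package's own
  experiments run the scaled configurations above.
* The power analysis assumes common marginals across arms; strongly
  asymmetric rating distributions need the bootstrap machinery instead.
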