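# Methods

`mindsct` implements structure-constrained unpaired translation between
chest MRI (ZTE-like contrast) and CT: cycle-consistent adversarial
translation (CycleGAN objective), attention-guided translation with
adaptive layer-instance normalisation and class-activation-map losses
(U-GAT-IT objective), and — the core of the package — a
modality-independent neighbourhood descriptor (MIND) consistency term that
penalises anatomical change across the modality swap.

## The descriptor

For an image `I`, pixel `x` and displacement `r` from a search set `R`,

    MIND(I, x, r) = (1/n) · exp( − D_p(I, x, x+r) / V(I, x) )

with the patch distance and local variance estimate

    D_p(I, x, x+r) = Σ_{p∈P} ( I(x+p) − I(x+r+p) )²
    V(I, x)        = Σ_{n∈N} D_p(I, x, x+n).

`n` normalises so the maximum over `r` equals 1 at every pixel.  Because
`D_p` and `V` are both quadratic in intensities, the descriptor is exactly
invariant to affine intensity maps `a·I + b` — it encodes local *geometry*
(edges, corners, blobs) rather than contrast, which is what makes it
comparable between MRI and CT.  The consistency loss is the mean absolute
difference of the descriptor stacks of an image and its translation,
averaged over pixels and channels (mean rather than sum, so λ_MIND does
not depend on image size).

Interpretation choices worth stating:

* **Offset sets.**  `R` defaults to the 81 shifts of the square (−4..4)²
  (one descriptor channel per shift), `P` to a 3×3 patch window, and `N`
  to the 4-connected neighbourhood, the 2-D analogue of the classical
  6-neighbourhood.  The descriptor literature also admits a reading in
  which the 81-shift set is the patch window; both sets are independently
  configurable (`MINDConfig`), and the 81-element property is a property
  of `build_shift_set(4)` under either reading.
* **Variance floor.**  The printed variance estimate can reach 0 (constant
  neighbourhoods), so `V` is clamped below at `1e-3 ×` its spatial mean.
  A *mean-relative* floor preserves the affine invariance exactly; an
  additional absolute guard (1e-30) only defines the constant-image limit,
  where every channel becomes exp(0) = 1.
* **Boundaries.**  Every out-of-bounds read clamps its own index to the
  edge (replicate).  The vectorised implementation builds `D_p` by
  shift-and-sum over cached clamped shifts, which makes it bit-identical
  to the per-pixel definition at *all* pixels, including borders; the test
  suite checks this against an independent nested-loop oracle.
* **Precision.**  Descriptor arithmetic runs in the input's float type
  (≥ 32-bit); oracle comparisons use float64.

## Objectives

Two generators (`G_ab`: MRI→CT, `G_ba`: CT→MRI) train against two patch
discriminators.  CycleGAN uses the log adversarial loss plus cycle
(`λ1 = 10`) and identity (`λ2 = 0.5`) L1 terms; U-GAT-IT uses the
least-squares adversarial loss plus the same consistency terms
(`λ1 = λ2 = 100`) and CAM losses (`λ3 = 100`) from auxiliary domain
classifiers in generators (log form) and discriminators (least-squares
form).  The MIND term enters the generator objective with `λ_MIND = 20`
(CycleGAN) or `5000` (U-GAT-IT) at clinical scale.  Batch reduction is the
mean; the two translation directions are summed; log-loss scores are
clamped to `[1e-7, 1 − 1e-7]`.

One printed form of the least-squares adversarial and CAM discriminator
losses places the square on `D(real)` and `1 − D(fake)`, which inverts the
usual least-squares convention and is inconsistent with the discriminator
*maximising* the objective.  The package follows the standard convention
(discriminator targets: real→1, fake→0; generator target: fake→1), which
matches the referenced U-GAT-IT formulation; the discrepancy is noted here
rather than silently absorbed.

The min–max problem is realised as alternating updates: one discriminator
Adam step on the full discriminator objective, then one generator step on
the full generator objective (Adam β = (0.5, 0.999), the values the
referenced implementations use; batch size 1).  The U-GAT-IT identity term
uses the same L1 form as the cycle term.  An image-pool replay buffer for
discriminator updates exists but is off by default.

## Networks

The generator is an encoder–bottleneck–decoder network: 7×7 stem, two
stride-2 downsampling stages, residual bottleneck with instance
normalisation; a CAM block whose auxiliary classifier weights re-weight
the bottleneck channels (rectified) and provide the domain logit; a
decoder of residual blocks normalised by AdaLIN,

    AdaLIN(x) = γ · ( ρ·IN(x) + (1−ρ)·LN(x) ) + β,   ρ ∈ [0, 1],

with γ, β predicted from the attended features and ρ a learned parameter
projected back into [0, 1] after every update; then nearest-neighbour
upsampling stages with layer-instance normalisation and a 7×7 head whose
tanh output is mapped to [0, 1] so synthesised images window like inputs.
Discriminators are stride-2 convolution stacks (leaky ReLU, spectral
normalisation via one step of power iteration, toggleable) with their own
CAM classifier and a per-patch realness head; one or two receptive-field
scales (the second sees a 2× average-pooled input).

No architecture hyperparameters are inherited from any specific
checkpoint: widths, depths and scales are configuration, defaulting to a
width-16 network at 64×64 (width 64 at 256×256 would be the clinical
setting; the desk protocol below uses width 8 at 32×32).

All networks, and the gradients of every objective term — including
gradients through the MIND descriptor (exponentials, the per-pixel channel
maximum, and clamped shifts) — run on a small reverse-mode autodiff tensor
engine over numpy (`mindsct.autodiff`), with im2col convolutions and
slice-adjoint backward passes for padding and shifting.  Every operation
is checked against numerical differentiation in the test suite.

## Synthetic phantoms

The phantom sampler emulates what unpaired MRI↔CT chest training needs:
two contrast domains over shared anatomy classes.  A body ellipse contains
two lung ellipses and small high-contrast bone elements (spine disc, two
humeral-head discs, 3–4 rib discs per side) — small on purpose, so Dice
and centroid metrics stay sensitive to misplacement at 32–64 px.
`ct_style` renders background/lungs/soft-tissue/bones at 0.0/0.08/0.35/0.90
(a windowed-CT look); `mri_style` at 0.0/0.25/0.75/0.05 (ZTE-like: bone
and air dark), times a smooth multiplicative bias field (strength 0.3,
bicubic from a 4×4 Gaussian grid) emulating coil sensitivity.  Additive
Gaussian noise (σ = 0.02) is applied after the masks are frozen.  Geometry
jitters per sample; all randomness comes from a counter-based Philox
stream keyed by (seed, style), so the two domains are disjoint streams and
samples are reproducible across platforms.

What the phantoms do *not* model: respiratory/cardiac motion, anatomical
texture inside tissues, partial-volume effects, scanner beds, 3-D
structure.  Passing the desk-scale tests therefore demonstrates that the
losses, optimisation and evaluation plumbing behave as designed — not that
clinical image quality is reproduced.

## Preprocessing

CT is windowed at WL 350 / WW 2000 HU onto [0, 1] (−650 → 0, 1350 → 1).
Background removal keeps the largest connected above-threshold component
and fills its holes.  MRI is normalised to the median in-mask tissue value
(median exactly 1 after division; an optional 99.5th-percentile cap maps
to [0, 1] for training).  A smooth multiplicative bias can be divided out
via a Gaussian low-pass estimate of the in-mask intensity (normalised
convolution) — a deliberately simple substitute for histogram-sharpening
bias correction, and toggleable.  Resampling is bilinear with pixel-centre
alignment and edge clamping.  I/O: PNG (8-bit), NIfTI, DICOM (rescale
slope/intercept applied on read, so CT reads return HU).

## Structural evaluation

The radiologist rubric maps major/minor bone-misalignment counts over a
six-image case set to 1–5 (rules in severity order: ≥10 major → 1;
≥5 major → 2; ≥3 major or ≥15 minor → 3; ≥1 major or ≥10 minor → 4;
else 5).  Reader counts cannot be automated, so the rubric is a pure
counts→score function, and quantitative proxies are computed against the
phantom ground truth: bone-mask Dice (synthesised CT thresholded at the
windowed value of 200 HU ≈ 0.425, components < 3 px removed), body Dice,
bone-centroid shift, and an inter-class contrast statistic
`|bones−soft| + |soft−lungs|` under the source masks, whose fall below
0.10 raises a contrast-collapse flag.  Rubric and proxies are reported
side by side, never conflated.  Method comparison uses the Wilcoxon
signed-rank test on paired per-case scores (Pratt zero handling; exact
distribution where scipy can compute it, normal approximation with tie
correction otherwise) with Bonferroni correction over the comparisons
actually performed, at α = 0.001.

## Desk-scale study protocol

The clinical comparison (150 patients, 256×256, 100–1000 epochs, GPU,
four radiologists) cannot be rerun on a desktop CPU.  `mindsct.study`
freezes a desk-scale analogue that one core runs in minutes: 32×32 phantoms, 16 training images per
domain, 10 held-out MRI phantoms, 300 generator updates per run, width-8
networks, one discriminator scale, training-time MIND at search radius 1.
Two parameters are re-calibrated for this regime and documented as such:

* **Learning rates** ×5 (CycleGAN 1e-3, U-GAT-IT 5e-4), preserving the
  published 2:1 ratio, because 300 updates must cover the optimisation
  distance of tens of thousands.
* **λ_MIND** 10 (CycleGAN) and 300 (U-GAT-IT).  The clinical weights are
  calibrated for radius-4 descriptors and long schedules; under the desk
  regime they dominate the generator objective so completely that CT
  contrast never emerges (the identity mapping is a MIND-optimal shortcut
  early in training).  The desk weights keep the MIND term the same order
  as the other generator terms.  The published weights remain the package
  defaults everywhere outside the study protocol.

The high-λ stress raises λ_MIND to 3× the desk default, mirroring the
clinical observation that tripling the CycleGAN+MIND weight (20 → 60)
collapses the synthesised contrast; collapse is detected by the contrast
statistic above.

Under this protocol the MIND variants achieve higher median held-out
bone Dice than their plain counterparts on a majority of seeds (the
desk-scale analogue of the clinical ordering), generator totals decrease
from the first to the last decile of training, and all components remain
finite; the acceptance-oriented tests assert exactly these properties.
Runs are bit-reproducible given (variant, with_mind, seed).

## Numerical and degenerate-input policy

* Scores/probabilities entering logs are clamped to `[1e-7, 1 − 1e-7]`.
* Normalisation layers use ε = 1e-5 inside the square root.
* Ties in the per-pixel channel maximum share gradient equally (relevant
  only on exactly constant neighbourhoods).
* Constant images: the descriptor is all-ones; `remove_background` raises
  on empty foreground; `normalize_mri` raises on a zero median.
* Non-finite loss components abort a training step with the component
  named in the error.
* Checkpoints store all parameters, both Adam states, spectral-norm
  power-iteration vectors and the batching RNG state, so an epoch-aligned
  resume reproduces an uninterrupted run's next step.

## Known limitations

2-D only; two domains only; no deformable-registration use of the
descriptor; the Gaussian bias stand-in is not a substitute for full bias
correction on real data; the phantom realism limits noted above mean
desk-scale orderings are an analogue of, not evidence for, clinical
performance; the rubric's reader counts are inputs, not outputs, of this
package.
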