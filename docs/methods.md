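# Methods

## Problem setting

`sitrans` performs conditional image-to-image translation on 2-D
grayscale medical-style images. Each image `x : Ω → R` carries a vector
of `m` continuous attributes `y` (for brain imaging, typically age and a
disease-severity score), any entry of which may be missing. A generator
`G(x, ỹ − y)` is trained to produce an image whose attributes appear to
take the target values `ỹ` while preserving everything unrelated to the
attributes. Conditioning on the *difference* `ỹ − y` rather than on `ỹ`
means a missing entry can simply be encoded as a zero difference
(`ỹ_k − y_k := 0` when either side is unobserved), so partially labeled
cohorts — the norm in clinical datasets — train without imputation.

## The spatial-intensity transform

Unconstrained generators synthesize the output image directly from the
last convolution, which on small or noisy datasets produces bright/dark
artifacts that can masquerade as pathology. The spatial-intensity
transform (SIT) instead makes the head emit:

* a **stationary velocity field** `V : Ω → R²`, integrated to a
  diffeomorphism `Φ_V = exp(V)` by scaling and squaring, and
* a **sparse intensity difference map** `Δx : Ω → R`,

applied as `Φ_V(x + Δx)` — the intensity change is added *before*
warping. The diffeomorphism captures morphology (ventricle growth,
sulcal widening), the sparse intensity map captures focal signal change
(lesion-like hyperintensities), and the two can be visualized separately.
The head adds no learnable parameters beyond the final convolution's
output channels, and forcing that convolution to zero makes the whole
generator the identity map — a strong robustness prior that the
unconstrained head lacks (it collapses to a zero image instead).

`Δx` is penalized by its mean absolute value
`‖Δx‖₁ = (1/|Ω|) Σ_ω |Δx(ω)|` with weight `λ_Δx = 10`. Raw
displacement heads (`st_disp`, `sit_disp`) additionally pay a discrete
total-variation penalty `‖F‖_TV = (1/|Ω|) Σ_ω ‖∇F(ω)‖₂` with
`λ_F = 1`; diffeomorphic heads need no smoothness term.

Six output parameterizations are implemented for ablation: `base`
(direct image), `it` (intensity map only), `st_disp` (displacement
field), `st_diff` (velocity field), `sit_disp` (displacement +
intensity), and `sit_diff` (velocity + intensity; the SIT proper).

## Numerical choices in the transform core

* **Integration.** `exp(V)` uses scaling and squaring with `n = 7`
  squarings by default (scale factor 1/128), configurable. Seven steps
  keeps per-step displacements sub-pixel for velocities up to several
  pixels; the number of squarings is a standard choice in
  stationary-velocity registration.
* **Interpolation.** All warps are bilinear with replicate
  (clamp-to-edge) boundary handling; zero padding would create halo
  intensities indistinguishable from intensity change. Grids are indexed
  `(row, col)`, 0-based, displacements in pixel units.
* **Velocity units.** `V` is the total displacement over unit time in
  pixels; scaling and squaring divides by `2^n`.
* **Oracle agreement.** Against an independently written forward-Euler
  flow integrator with `2^7` substeps, the scaling-and-squaring
  integrator agrees to ~0.03 px (max over the grid) for random fields
  with 6 px correlation length and magnitude ≤ 4 px on a 64² grid. Both
  integrators share bilinear sampling error, which grows with field
  roughness: at 4 px correlation length the deviation reaches
  ~0.05–0.07 px. Test fields use a 6 px correlation length (about 10% of
  the frame — the scale of anatomical deformations) and taper to zero at
  the border, since clamp-to-edge sampling makes boundary-crossing flows
  non-invertible at the edge.
* **TV scheme.** Forward differences with replicate edge (last row/col
  difference = 0); the 2-norm is taken jointly over all four partial
  derivatives per pixel (the isotropic reading of `‖∇F‖₂`). The
  differentiable version adds `1e-16` inside the square root to avoid an
  infinite gradient at exactly-constant fields; the user-facing
  `displacement_tv` is exact.
* **Diffeomorphism diagnostic.** `jacobian_determinant` evaluates the
  central-difference Jacobian of `ω ↦ ω + u(ω)` on the interior grid;
  positivity certifies local invertibility.

## Differentiation engine

The package trains its networks with a small, self-contained
reverse-mode automatic-differentiation engine on numpy arrays
(`sitrans.autodiff`). Every primitive's vector-Jacobian product is
itself written in terms of the engine's primitives, so gradients are
ordinary graph nodes and second derivatives are available — required
because the Wasserstein critic's gradient penalty differentiates the
critic's input-gradient norm with respect to the critic weights.
Convolution VJPs are convolutions (flipped-kernel for the input, a
batch-contracted correlation for the weights), verified against central
finite differences, including second order through conv + ReLU chains.
Computation is float64 throughout.

## Architectures

* **Generator.** A 2-D U-Net: `resolutions` spatial levels (default 4)
  with channels doubling to `bottom_channels` (default 128) at the
  coarsest level; two 3×3 conv → batch-norm → ReLU pairs per level; 2×2
  max-pool down, bilinear ×2 up; He initialization. The bottleneck is
  flattened through a fully connected layer into a 50-dimensional latent
  vector; `Δy` is concatenated to that vector and additionally
  broadcast as constant channels into the two coarsest decoder levels
  (conditioning should steer global structure; the injection points are
  configurable). The output head is a linear 1×1 convolution with 1, 2
  or 3 channels depending on the parameterization.
* **Critics.** VGG-like: three (conv → BN → ReLU → max-pool) blocks,
  then a hidden fully connected layer feeding a scalar logit.
  Conditional critics receive the attributes broadcast as constant input
  channels. The multi-attribute (StarGAN-style) framework shares this
  trunk between the discriminator logit and an m-output attribute
  regression head. Batch normalization is kept in the critics (the
  recipe applies BN after all convolutions); the gradient penalty is
  computed per sample.
* **Latent adversary** (adversarial-autoencoder framework): a 3-layer
  MLP on the 50-d latent, driving the encoder output toward a uniform
  prior on [0, 1]⁵⁰ with the same Wasserstein + gradient-penalty recipe
  as the image critic.

## Training frameworks

All four frameworks share the training recipe: Adam (β₁ = 0.5), learning
rate 1e-3 (the adversarial-autoencoder's critics use 1e-4), minibatch 8,
up to 10 000 iterations, one critic update then one generator update per
iteration. Target attributes `ỹ` are drawn from the dataset's empirical
attribute vectors, never invented.

* **rgae** — generator + attribute regressor: relative-attribute loss
  `(1/m)‖(R(G(x,Δy)) − R(x)) − Δy‖²` plus cycle consistency
  (`λ_cc = 0.1`). The regressor trains on real pairs only with a
  masked MSE.
* **caae** — encoder/conditional-decoder generator, conditional image
  critic (WGAN-GP, `λ_GP = 1`), latent adversary, reconstruction term
  `‖G(x,0) − x‖₁` (`λ_rec = 0.1`), and a conditional correction
  (`λ_cond = 1`) that makes the critic prefer the real image with its
  true attributes; a sign switch is exposed because the direction
  convention is a modeling choice.
* **ipgan** — conditional critic plus an identity-preservation term
  `‖G(x,Δy) − x‖² · exp(−|y₀ − ỹ₀|)` (`λ_ID = 0.1`, `λ_rec = 1`); each
  minibatch trains either the reconstruction loss or the
  adversarial+conditional+identity set, chosen by a fair seeded coin
  (memory-saving split). The age-like attribute is index 0 by
  convention, configurable.
* **stargan** — unconditional critic and regressor sharing a trunk,
  updated jointly as `L_D + λ_R L_R` (`λ_R = 10`); the generator
  minimizes adversarial + `0.1`·cycle + `10`·relative-attribute losses.

Gradient-penalty interpolates are per-sample convex combinations of real
and translated images; conditional critics score interpolates with the
*real* image's attributes (attribute interpolation is ill-defined with
missing entries). Training batches (and only training batches) are
augmented with horizontal flips (p = 0.5), small affine jitter
(rotation ≤ 5°, translation ≤ 3 px, scale 0.97–1.03) and intensity
scaling (0.9–1.1).

A master seed fans out to independent PCG64 streams (init, batch,
targets, augmentation, gradient-penalty, coin, prior), making full runs
bit-reproducible; checkpoints store network weights, optimizer moments
and all stream states, so a resumed run reproduces the uninterrupted one
exactly.

## Synthetic phantom cohorts

The generator's ground-truth testbed renders axial-slice-like phantoms:
an elliptical head with smooth tissue texture, dark radial sulci, a
central dark "ventricle" of radius `r₀ + α_r·a₁` (defaults 6 px and
1.5 px per unit at the 64-px frame; all pixel quantities scale with
frame size), and bright lesions placed on a ring just outside the
ventricle boundary whose count and extent grow with `a₂`
(base 2, +1.5 per unit). Placing lesions against the ventricle border
deliberately entangles the intensity effect with the morphology effect,
so disentangling them is a non-trivial test. Structure boundaries are
smooth (≈0.7 px sigmoid edges), images are blurred (σ = 0.8 px), noised
(additive Gaussian, σ = 0.02) and clipped to [0, 1]. Attributes live in
[−2, 2]; cohort sampling draws subject baselines ~N(0, 0.8) and advances
the age-like attribute by 0.25 units/year along each subject's
timepoints (~1 year apart), with subject-level anatomy (head jitter,
sulci, texture) held fixed across timepoints. Attribute normalization to
zero mean / unit sd is fitted on the observed values and carried by the
dataset.

An analytic radial deformation (`ground_truth_deformation`) maps the
phantom at one attribute value onto another — linear contraction inside
the ventricle, linear relaxation to the identity at the head boundary —
and warps a morphology-only phantom onto its re-rendered counterpart
with RMSE < 0.02, with positive Jacobian across the documented range.
It serves as a supervised oracle for transform-recovery tests.

What the phantoms do *not* emulate: MRI physics (bias fields, motion,
partial volume), 3-D anatomy, multi-modal contrast, or realistic
population covariance between attributes. Passing tests on phantoms
demonstrates that the estimator recovers known attribute-to-image links
under controlled conditions, not clinical performance.

## Evaluation metrics

* **RMSE / DSSIM** compare predicted to ground-truth images of
  longitudinal pairs (≤ 5 ordered pairs per subject, separated by at
  least one year, seeded selection). DSSIM = (1 − SSIM)/2 with a 7×7
  uniform window and constants C₁ = (0.01 L)², C₂ = (0.03 L)²
  (L = intensity range): identical images score 0, patchwise
  uncorrelated images ≈ 0.5.
* **Fréchet feature distance** between Gaussian fits of embedded real
  and generated sets; the covariance square root uses an
  eigendecomposition with negative eigenvalues clipped at zero, and
  covariances are ridge-regularized when sample counts fall below twice
  the feature dimension.
* **PRD** precision (F_{1/8}) and recall (F_8): k-means on the pooled
  embeddings (20 clusters, scaled down for small samples; seeded),
  two histograms over cluster assignments, and the PRD curve on a
  1001-point angular grid.
* **Embedder.** FID-style metrics conventionally embed with a
  pretrained Inception-v3; to keep this package dependency- and
  download-free the default embedder is a small convolutional encoder trained on the
  synthetic cohort with an attribute-regression objective (a seeded
  random-projection embedder is available as a fast fallback). FID/PRD
  values are therefore embedder-relative; reports record the embedder's
  provenance and sample counts.
* **AgeError**: an evaluation regressor — deliberately different from
  any regressor used during training — predicts the age-like attribute
  of translated images; the mean ± sd of (estimate − target),
  de-normalized to natural units, measures target-attribute matching.

## Problem sizes used by the test suite

The full suite must run quickly on one CPU, so training-based checks run
at reduced scale, chosen once as the package's own desk-scale
conditions: the parameter-recovery experiment trains SIT-StarGAN
(`sit_diff`) on a 300-phantom 32×32 cohort (U-Net with 16 bottom
channels, 4 integration steps, batch 8, 1500 iterations) and checks that
the measured ventricle radius increases monotonically along an
attribute sweep of ±1.2 normalized units on at least 8 of 10 held-out
subjects, and that a ridge evaluation regressor puts the mean AgeError
below 0.5 attribute units. The determinism matrix runs every framework ×
parameterization combination twice for 100 iterations at 8×8 with
4-channel networks and asserts bitwise-identical loss logs.

## Known limitations

* 2-D only; velocity fields are emitted at full resolution (a coarser
  parameterization with upsampling is a possible variant).
* No exact deformation inverse is computed; invertibility is checked
  numerically (compose-with-negated-velocity, Jacobian positivity).
* The numpy engine is single-threaded-friendly but 1–2 orders of
  magnitude slower than GPU frameworks; clinical slice resolutions
  (~224×192) are out of desk reach, which is why the test suite
  validates at phantom scale.
* Batch normalization in Wasserstein critics couples samples within a
  batch; the recipe retains it deliberately, but it is a known deviation
  from common WGAN-GP practice.
* FID/PRD numbers are not comparable across embedders; only within-run
  comparisons (e.g. between parameterizations under the same embedder)
  are meaningful.
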