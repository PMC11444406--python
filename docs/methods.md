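# Methods

## Model

### Cell state and update rule

The segmenter is a neural cellular automaton: every pixel carries a
channel vector `(image, logit, hidden…)` and all pixels share one small
update network applied iteratively.  A step computes an update field
from a local neighbourhood and adds it to the state at a random subset
of cells ("firing", Bernoulli with rate `fire_rate`, mask shared across
a cell's channels so a cell fires as a unit).  The input-image channel
is never modified by updates, so the evidence the automaton reasons
about is stationary.

Two rule shapes are used:

* **base block** (refinement scales, k = 3): perception convolution →
  1 × 1 dense mixing → batch norm → ReLU → linear 1 × 1 projection back
  to the state channels.  The trailing linear projection is required so
  updates can be signed; a rule ending in ReLU could only ever grow the
  state.
* **fused wide block** (coarsest scale): k = 7 perception convolution →
  batch norm → ReLU → k = 3 output convolution.  The wide kernel buys a
  large receptive field where the grid is small; the k = 3 output layer
  adds fine spatial mixing.  Its one-step receptive-field radius is
  ⌊7/2⌋ + ⌊3/2⌋ = 4.

Information propagates at most `steps × radius` pixels — an invariant
the test suite checks by perturbation.

Output projections are initialized with small random weights (SD 0.02)
rather than exact zeros.  Exact zero-init of both the projection and the
classification layer creates a gradient deadlock: the loss then depends
on the state only through zero classifier weights, and on the rule only
through zero state derivatives, so no NCA parameter would ever train.
Near-zero init keeps the untrained rule close to the identity map (the
usual NCA stabilization) while letting gradients reach every layer.

### Recurrent batch normalization

The rule is applied recurrently, and the activation statistics of step
*t* differ systematically from step *t + 1* (the state grows as updates
accumulate).  Sharing one running mean/variance across steps makes
eval-mode inference diverge from training behaviour — in our experiments
training-mode Dice ≈ 0.8 collapsed to ≈ 0 at inference.  We therefore
keep **per-timestep running statistics**: batch statistics are used (and
per-step running estimates updated, momentum 0.1) during training, and
the step-indexed running estimates at inference.  If inference runs more
steps than were ever trained, the last available statistics are reused.

### Multi-scale pipeline

With downscaling factor `d` and `n` iterations, each level shape is the
previous one floor-divided by `d` (the volumetric worked example
`[640, 640, 48] → [40, 40, 3]` for d = 2, n = 4 is exact under floor
division).  Inputs whose sides are not multiples of `dⁿ` are edge-padded
up front and the output cropped back, so every internal level shape is
exact.  The forward pass:

1. area-average downscale the image to the coarsest level and run the
   fused rule for `steps_coarse` iterations;
2. per refinement level: upsample the **full** cell state by `d`
   (nearest-neighbour — its adjoint is an exact block sum, which keeps
   backpropagation cheap and exact), overwrite the image channel with
   the true image at that level, and run the base rule for `steps_fine`
   iterations.  During training the state is first cropped to a random
   aligned patch of the coarsest-level size, so full-resolution
   gradients are never materialized; at inference full frames are
   processed;
3. at the final level, apply the shape-guided block (below), then a
   shared 1 × 1 classification layer and a sigmoid.

The combined loss is evaluated at every level (through the shared
classifier) and averaged, with an optional extra weight on the final
level (`final_loss_weight`, default 1 = equal weighting).  Mask targets
at coarse levels are area-averaged, i.e. soft.

### Shape-guided block

SLIC over-segments the guidance image (the input at the current level)
into `n_segments` superpixels; the feature state is mean-pooled within
each superpixel and the pooled vector broadcast back over its support;
the smoothed state is added residually.  Mean pooling makes
unpool∘pool an orthogonal projection (so the block is idempotent on
piecewise-constant states, and its backward pass is the same smoothing
operator); max pooling is available behind a flag.  The superpixel
assignment is treated as non-differentiable (stop-gradient through the
labels); gradients flow through the pooled values.  SLIC compactness
defaults to 0.2, calibrated for unit-range images — compactness trades
intensity distance against spatial distance, so values quoted for
uint8-range images (≈ 10) degenerate to a fixed grid on [0, 1] inputs.
`n_segments` defaults to 100 per 256² pixels, scaled with area.

### Training loop

Adam on the combined loss `α·DiceLoss + (1−α)·BCE` (α = 0.5 by default;
soft Dice with ε = 1e−6 smoothing in training, hard Dice thresholded at
0.5 for reporting).  Each batch is duplicated `duplication` times —
identical copies whose stochastic firing decorrelates, which stabilizes
NCA gradients.  An "epoch" is `steps_per_epoch` minibatch optimization
steps (default: one full pass).  A validation split
(`validation_fraction`, default 20 %) is monitored every epoch; training
stops when the validation loss has not improved for
`early_stop_patience` epochs (default 20) and the best snapshot is
restored.  Validation predictions average two stochastic passes so the
stopping signal tracks the model rather than the firing noise.  A
checkpoint is kept every `checkpoint_every` epochs (default 10) and
restored if the loss ever becomes non-finite.  The reference recipe's
learning rate 1.5625e−5 with up to 3000 epochs remains the `TrainConfig`
default; it pairs a very small step size with a very long schedule and
is impractical for the desk-scale runs below.

### Inference and quality assurance

Firing makes inference stochastic.  `predict_proba` can average
`inference_runs` passes (a pseudo-ensemble); the QA module exposes the
full per-run stack.  The NCA quality metric normalizes total per-pixel
deviation by total predicted mass:

    NQM = Σ SD(pixel) / Σ μ(pixel),  SD population (divide by n).

It is exactly 0 when all runs agree (we snap the exact-agreement case to
zero to avoid float residue), scale-invariant, undefined when the mean
prediction is identically zero (reported as missing, never as 0), and
computed on probabilities by default (a binarized variant is a flag).
QA reports default to 10 runs — enough for a stable score at desk scale;
the ensemble size is configurable into the thousands.

## Synthetic phantoms

The generator emulates the structure that makes mammographic lesion
segmentation hard at small scale: a stationary textured background
(Gaussian noise smoothed with a kernel of width `texture_scale`) plus
bright lesions — ellipses with a low-order radial Fourier perturbation
(axis ratio ≥ 0.75, total boundary perturbation ≤ 15 % of the radius)
whose image edge is blurred by `boundary_sigma` while the ground-truth
mask keeps the crisp pre-blur support.  Overlapping lesions union in
the mask.  Contrast is the lesion's mean elevation in units of the
realized background SD — a contrast-to-noise ratio.

`texture_scale` defaults to 1.5 px against a minimum lesion radius of
6 px.  This separation matters: the per-pixel CNR of 3 makes plain
thresholding mediocre regardless of texture scale (≈ 0.6–0.7 Dice), and
detectability then hinges on spatial integration over the lesion area
(Rose-criterion reasoning — effective SNR grows with the square root of
the lesion-to-correlation-cell area ratio).  With background grain well
below the lesion scale a spatially integrating model can segment
reliably; with grain at the lesion scale (e.g. 4 px against 6 px radii)
background blobs become intrinsic lesion mimics and even per-image
oracle thresholding fails, which would say nothing about the model.

What the phantoms do **not** emulate: anatomy (pectoral muscle, skin
line, vasculature), calcifications, non-stationary parenchymal texture,
scanner-specific noise, or multi-modality intensity profiles.  Passing
tests demonstrate that the pipeline learns, that shape guidance helps on
blurred-boundary blobs, and that the quality metric responds to
distribution shift — not clinical performance.

## Preprocessing

Resize (bilinear for images, nearest for masks; default 256 × 256) →
per-image standardization (population SD; constant images are an error)
→ z-score clamp to ±`clip_bound` (default 5) — the outlier-removal
reading of cropping "at [5, 5]", chosen because a border crop would not
remove deviating values — → affine rescale to [0, 1].  Elastic
deformation (Gaussian-smoothed uniform displacement field; `alpha` = 34,
`sigma` = 4 at 256², the standard construction) warps image and mask
with one shared field, bilinear/nearest respectively, and is a
training-time augmentation only.

## Evaluation metrics

Pixel accuracy, hard Dice, class-averaged IoU (foreground and
background; empty-vs-empty defined as 1 by the ε convention), and HD95 —
the max of the two directed 95th percentiles of boundary-to-boundary
nearest-neighbour Euclidean distances (the dominant convention in
medical-segmentation benchmarking), computed via exact distance
transforms, scaled by pixel spacing when metadata provides it, and
undefined (missing, not 0) for empty masks.

## Numerical and implementation choices

* The NCA runs on a purpose-built numpy reverse-mode autodiff engine
  (float32; convolution as a sum of shifted 1 × 1 matmuls, whose
  backward pass reuses the same slice structure).  Gradient checks
  against hand-rolled oracles are part of the test suite.
* Probability clamp 1e−7 inside BCE logs; BCE on logits uses the
  softplus-stable form.  Dice smoothing ε = 1e−6.
* Binarization threshold 0.5, configurable.
* Coordinates are row-major, 0-based (row, col); pixel spacing defaults
  to 1.0 (HD95 then in pixels).
* Model checkpoints are single `.npz` files with the estimator
  configuration embedded as JSON; a save → load round trip reproduces
  forward outputs bit-for-bit under a fixed RNG.
* Dataset items derive per-item seeds from one generator stream, so
  collections are reproducible and items independent.

## Desk-scale problem sizes

The end-to-end checks train on 200 phantoms (64², one lesion at
contrast 3) with a deliberately small configuration: 8 hidden channels,
rule width 16, d = 2 with n = 2 levels (coarsest 16², training patches
16²), 6 coarse / 6 fine steps, 32 superpixels, Adam at 3e−3, batch 4
with duplication 2, 5 optimization steps per epoch, at most 100 epochs
with patience 20, pseudo-ensemble inference with 4 runs.  These sizes
are the package's chosen study conditions for CPU-scale verification;
under them the shape-guided model reaches mean held-out Dice ≥ 0.8 and
outperforms its no-SGB ablation on most seeds, mirroring the direction
of the full-scale comparison without claiming its numbers.

## Known limitations

* 2D only in practice; the operators are written over NCHW grids and
  would extend to 3D, but no 3D path is exercised.
* The learning rate that suits the desk-scale recipe (3e−3) is three
  orders of magnitude above the reference recipe's; transferring the
  package to real mammograms requires re-tuning.
* Per-timestep batch-norm statistics tie the inference step count to
  the trained step count (extra steps reuse the last statistics).
* SLIC runs per image and per scale at inference; for large images the
  superpixel step dominates runtime.
* NQM is a relative deviation measure: it is undefined on images where
  the model predicts no foreground at all, and its absolute scale
  depends on the model and task, so review thresholds must be
  calibrated per deployment.
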