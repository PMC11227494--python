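# Methods

## The pretraining objective

The package learns representations of echocardiogram videos without
labels by combining two self-supervised signals.

**Multi-instance contrastive learning.** A routine transthoracic
echocardiogram (TTE) study usually contains several distinct videos of the
same view.  Instead of manufacturing two "views" of one video with heavy
augmentation — which destroys diagnostic signal in low-contrast ultrasound
— two genuinely different videos of the same study form a positive pair.
Given a batch of N pairs, each clip is encoded by a 3D CNN f into a
512-dimensional representation h and projected by a two-layer MLP g
(512 → 256 → ReLU → 128) into an embedding z.  The batch of 2N embeddings
is scored with the temperature-normalized cross-entropy (NT-Xent) loss

    l(i,j) = -log [ exp(sim(z_i, z_j)/τ) / Σ_{k≠i} exp(sim(z_i, z_k)/τ) ]

where sim is cosine similarity and τ = 0.5; the batch loss averages l over
both orderings of every pair.  Because only cosine similarities enter, the
loss is invariant to a global rescaling of the embeddings, and for
mutually identical embeddings it collapses analytically to ln(2N−1) — a
closed form the tests pin down.

**Frame-order prediction.** Each K-frame clip (K = 4 by default) is
randomly permuted along time before encoding, and a single linear head on
h must classify which of the K! = 24 orderings was applied (orderings are
indexed by their lexicographic rank via the Lehmer code).  Chance level is
exactly ln K! in loss and 1/K! in accuracy.  K = 4 keeps the target space
small and a clip short enough that it rarely spans repeated phases of the
cardiac cycle, which would make the ordering ambiguous.

The combined objective is the unweighted sum of the two terms.  Ablation
modes are first-class: `misimclr` drops the reorder term, `simclr`
additionally drops multi-instance sampling (two independently augmented
copies of one clip form the pair instead).  When comparing the
single-video mode against the pair modes, the epoch budget is rescaled by
round(pair_epochs × pairs/items) so both see the same number of examples.

## Encoders

The default encoder is an 18-layer 3D residual network (3×7×7 stem with
spatial stride 2, then four stages of two basic blocks at 64/128/256/512
channels, with spatiotemporal stride 2 in stages 2–4, global average
pooling to h ∈ R^512).  On a 3×32×112×112 clip the last convolution block
emits a 512×4×7×7 grid.  Grayscale clips are replicated to three channels
to satisfy the stem.

All layers (3D convolution via im2col with analytically derived backward
passes, batch normalization, ReLU, linear, global pooling) and the Adam
optimizer are implemented on NumPy in `echoclr.nn`; every backward pass is
verified against finite differences in the test suite, and runs are
bit-reproducible given the config seed.  A reduced encoder (`tiny`: three
conv/BN stages at 8/16/32 channels, followed by a linear lift to the same
512-dimensional representation space) is a first-class configuration for
CPU-scale experiments; projector and heads are encoder-agnostic.

## Data pipeline

* **View classification** averages frame-level probabilities from a
  pluggable classifier over 10 randomly sampled frames (resized to 224²)
  and keeps a video iff the argmax class is PLAX.  No classifier weights
  ship with the package.
* **Content masking** binarizes the union of frames at intensity ≥ 200,
  takes the convex hull of the largest bright contour, and zeroes all
  pixels outside it.  The hull is computed once per video (per-frame hulls
  would jitter the field of view over time); the ≥ comparison includes
  saturated pixels.  The operation is idempotent and never increases any
  pixel value.
* **Downsampling** is bilinear to 112² (configurable).
* **Splitting** is at the study level: shuffled ids, first ⌊0.75 n⌋ train,
  next ⌊0.10 n⌋ validation, remainder test.
* **Titration** draws ⌊ratio·n⌋ studies uniformly without replacement;
  the floor rule is the only rounding consistent with every published
  count (e.g. 5194 × 0.10 → 519, 5311 × 0.25 → 1327).  Titration is not
  label-stratified.
* **Clips** are K consecutive frames with a uniform random start; videos
  shorter than K are looped (t ↦ t mod T), which preserves periodic
  motion.  Intensities are rescaled to [0, 1].
* **Augmentation** draws one transform per clip — zero padding up to 8 px
  per spatial dimension followed by a size-preserving random crop, a
  horizontal flip with probability 0.5, a rotation in (−10°, 10°) with
  probability 0.5 — and applies it identically to every frame.  Per-frame
  independent geometry would corrupt the temporal signal the reordering
  task depends on.

## Fine-tuning and evaluation

Fine-tuning trains a binary disease head (sigmoid + cross-entropy) on
16-frame clips, with the same augmentations, from one of three encoder
initializations: random, an SSL checkpoint, or externally supplied
Kinetics-400 weights (in which case clips are standardized with the
Kinetics channel means/stds; the weights themselves are never downloaded).
Training runs at most 30 epochs with early stopping: if validation loss
fails to improve for 5 consecutive epochs, training stops and the weights
from the best epoch are restored.  Learning-rate grids depend on the
initialization and titration ratio — SSL {0.1, 0.05, 0.001} and
random/Kinetics {1e-4, 5e-5, 1e-5} at ratios ≤ 10%, single rates above —
and the grid entry with minimal validation loss at its early-stopping
checkpoint is selected, ties going to the larger rate.

Labels describe studies but models score videos, so video scores are
averaged into one study-level score before metrics.  AUROC is the
Mann-Whitney statistic (ties count 1/2), AUPR is step-wise average
precision.  Confidence intervals use the percentile bootstrap over study
resamples (default B = 10,000; single-class resamples are redrawn and
logged; the bootstrap AUROC kernel is a vectorized rank computation that
the tests verify against the public metric exactly).  Differences between
two models on the same studies use a one-sided bootstrap z-test: the
observed AUROC difference divided by the bootstrap SD of paired resampled
differences, referred to the upper normal tail (B = 2000 by default).

## Saliency

Grad-CAM on the last convolution block: channel weights are the gradient
of the positive-class pre-sigmoid logit, global-average-pooled over the
full space-time grid (the canonical 2D recipe extended to 3D); the
ReLU-rectified weighted activation sum gives a height × width × time grid
(7×7×4 for the default encoder on a 32-frame 112² clip), which is
spline-interpolated (order 3, with negative overshoot clipped at zero) to
112×112×32 and collapsed to a 2D map by the pixelwise maximum over time.

## The synthetic cohort

Hospital echo data cannot be shared, so `echoclr.fixtures` generates
cohorts carrying the statistical structure the method needs:

* a sector-fan geometry (apex top-centre, half-angle 30–45°) with pixels
  exactly zero outside the fan;
* a bright ring ("ventricle wall") whose radius oscillates sinusoidally
  with a configurable period (default 16 frames at 30 fps ≈ 110 bpm) and
  amplitude 10–16% of the radius, i.e. 20–32% peak-to-peak — in the range
  of physiological fractional shortening;
* multiplicative speckle (default σ = 0.25) that is *tissue-locked*: 80%
  of the noise variance is a fixed per-video field and 20% varies per
  frame, mirroring how real speckle rides on the anatomy and decorrelates
  slowly.  Under purely white per-frame noise the frame-ordering task is
  unlearnable at desk resolution, because the sub-pixel wall motion
  between adjacent frames is swamped;
* per-study acquisition latents (fan geometry, ring radius and brightness,
  wall thickness, background level) shared by all videos of a study, which
  is what makes two videos of one study a meaningful positive pair;
* a planted structural disease signal: diseased studies get a thicker
  ring wall (default +2.0 px on a ~2 px base, the "large effect"
  condition).  The signal is geometric rather than textural so spatial
  preprocessing cannot erase it, mirroring hypertrophy's definition.

Labels follow clinical rules: LVH iff the left ventricular mass index
strictly exceeds 95 g/m² (women) or 115 g/m² (men); severe aortic
stenosis by binarizing an ordinal grade (everything but "severe" is
negative).  A configurable fraction of studies (default 10%) lacks the
LVMI measurement: they keep a null LVH label, stay available for
pretraining, and are skipped during supervised fitting — reproducing the
differing task denominators seen in practice.  A small fraction carries a
generic exclusion flag (`llg_as`) that manifest filtering can remove.
Videos round-trip losslessly through an uncompressed 8-bit palettized
RIFF/AVI writer/reader, so on-disk cohorts are bit-exact.

What the fixtures deliberately do **not** model: beamforming physics,
Doppler, valve leaflets, off-axis probe motion, inter-vendor intensity
profiles, or non-PLAX views.  Passing tests therefore demonstrate that
the implementation learns the structures it is designed to learn under
controlled conditions — not clinical-grade performance on real
echocardiograms.

## Desk-scale benchmark conditions

`echoclr.experiments` fixes one canonical CPU-scale configuration: a
300-study cohort at 64² and 32 frames/video (prevalence 0.3, effect 2.0),
the 0.75/0.10/0.15 study-level split, 20 epochs of reduced-encoder
EchoCLR pretraining with Adam at lr 3e-3 and 16-clip batches (the
published lr of 0.1 at batch 392 is tuned for the full encoder at GPU
scale and diverges on the reduced encoder), and a 5%-titration comparison
of SSL-initialized vs randomly initialized fine-tuning over five seeds,
using one rate per initialization drawn from the published grids (0.001
and 1e-4).  Pretext quality is measured as exact-ordering accuracy on
validation clips (chance 1/24) and positive-pair top-1 retrieval among
validation videos (chance ≈ 1/(n−1) per anchor).

## Numerical choices and edge cases

* Floating point: parameters and activations are float32; losses and
  their analytic gradients are computed in float64.
* Batch norm: eps 1e-5, momentum 0.1; eval mode uses running statistics.
* The frame-reorder head is zero-initialized so it opens at the uniform
  distribution (loss exactly ln K!): with a large random init the early
  reorder gradients are dominated by spuriously peaked logits, which
  delays the pretext task's take-off under co-training.
* Hull masking with no pixel at threshold returns the video unchanged
  with a warning; degenerate (single-class) fine-tuning subsets and
  zero-norm embeddings raise typed errors.
* The bootstrap p-value at zero bootstrap SD is 0.5 for a zero observed
  difference and 0 or 1 otherwise, by sign.
* Every stochastic operation takes a seed (or Generator) and is a pure
  function of (inputs, seed).

## Known limitations

* The NumPy engine is single-threaded BLAS-bound; the full 3D-ResNet18 is
  practical for forward passes and Grad-CAM but not for full-scale
  pretraining, which is what the reduced encoder is for.
* The frame-reorder task on the fixtures is ambiguous up to time reversal
  within monotone windows of the sinusoidal cycle, capping achievable
  ordering accuracy well below 1; the diagnostics therefore test *above
  chance*, not near-perfect ordering.
* Retrieval and ordering diagnostics use one clip per video; study-level
  retrieval with multi-clip averaging would be less noisy but slower.
* Under co-training, reorder learning shows a plateau followed by a
  seed-dependent take-off: the contrastive branch — which pulls two
  differently-shuffled clips together and therefore rewards
  order-invariance — converges within a few epochs on the easy fixture
  cohort, and whether the encoder develops order-sensitive features
  before that pressure dominates varies with the cohort/initialization
  seed.  Within a 20-epoch budget some seeds have not taken off; longer
  schedules resolve this, as does the zero-initialized head (adopted).
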