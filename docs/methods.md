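# Methods

## Problem and model

Retinal vessel segmentation is a per-pixel binary classification of
fundus photographs: vessel versus background, evaluated inside the
circular field of view (FOV). The network implemented here is a
lightweight U-Net-style encoder–decoder whose design goals are a hard
trainable-parameter budget of 172,000 and preservation of thin-vessel
detail.

The contracting path is a 3×3 conv stem followed by three encoder
blocks, each conv → ReLU → batch-norm, with max-pooling only after the
first two blocks; limiting the network to two poolings keeps the deepest
features at 1/4 resolution so 1–2 px capillaries are not erased.
Between the encoder and the bottleneck sits the multipath
feature-extraction block: two consecutive stages, each of which runs
three parallel conv → ReLU → batch-norm paths with kernel sizes
n = 2k−1 for k = 1..3 (1×1, 3×3, 5×5) and sums the three outputs
elementwise. Summation (not concatenation) forces all paths to a common
width and keeps the parameter count low while mixing receptive fields.
A 1×1 bottleneck feeds the expanding path: two stride-2 transpose-conv
upsamplings with forward skips (encoder features concatenated before
the decoder conv, standard U-Net practice), a third full-resolution
decoder block, and a 1×1 softmax head over two classes.

Bidirectional skips: besides the two forward skips, decoder features
after the first decoder block are projected by a 1×1 conv, upsampled
(nearest-neighbour) to the first encoder block's resolution, and added
onto its stored feature map before the second decoder block consumes
it. This "reverse" connection refines encoder features with decoded
context while keeping the computation graph acyclic — the refined map
feeds only later-executing merges; the test suite asserts acyclicity by
topological sort.

Operator order inside every block is conv → ReLU → batch-norm. Placing
normalisation after the activation is less common than the reverse but
is the composition the block equations specify, and it is applied
uniformly so the choice is deliberate rather than accidental.

## Channel plan and parameter accounting

Default widths: stem 8; encoder 8/16/32; multipath 32; bottleneck 32;
decoder 32/16/8; head 2. These give 105,178 trainable parameters —
comfortably inside the 172,000 budget, which is the normative
constraint (the published figure is a budget, and the exact per-layer
widths behind it are not recoverable). Parameter accounting is done
twice and must agree exactly: a closed-form table (k²·C_in·C_out +
C_out per conv or transpose conv, 2·C per batch-norm) and the sizes of
the arrays actually allocated. Exceeding the budget is a build-time
error that carries the per-layer table.

Ablation variants mirror the design's three axes: `lightweight_baseline`
(no multipath block, no reverse skip, 32,658 params), `lbl_mfeb`
(+multipath, 104,914), `full` (105,178), and `baseline_unet`, a wider
classic U-Net reference (~0.51 M) exempt from the budget check.

## Compute backend

Layers, backpropagation and Adam are implemented in NumPy
(`lmbisnet.nn`): im2col convolutions (stride 1, same-padding),
non-overlapping 2×2 stride-2 transpose convolutions, 2×2 max-pooling
with first-maximum tie-breaking, and batch normalisation with batch
statistics in training and running estimates (momentum 0.1,
epsilon 1e-5) at inference. Weights are Glorot-uniform, batch-norm
scale 1 / shift 0, all drawn from a single seeded generator. Every
backward pass is validated against centred finite differences, and
convolution forward passes against scipy correlation, in the unit
tests. Default arithmetic is float32; float64 is available and used in
the gradient-check tests.

## Training recipe

Soft dice loss on the vessel-class probability,
L = 1 − (2·Σpg + ε)/(Σp + Σg + ε) with ε = 1.0 (ε smooths the
all-background case; F1 on binary masks equals 1 − L in the ε→0 limit).
Adam (β₁ = 0.9, β₂ = 0.999, eps = 1e-7) at initial lr 0.001; a ceiling
of 50 epochs ("iterations" in the source recipe is read as epochs,
consistent with per-epoch training-time reporting); the lr is halved
after 7 consecutive epochs without validation-dice improvement
(floor 1e-6); early stopping (default patience 15 epochs, unstated in
the source and therefore configurable) restores the best-validation
weights. Batch size defaults to 2, memory-safe at 512×512 on a CPU.
Validation for fixed-split datasets defaults to a seeded 10% of the
training set.

### Learnability smoke test

The acceptance suite checks that the full network can overfit two
synthetic 128×128 images to dice ≥ 0.9 within 200 optimiser steps
(majority of 3 seeds). Two bounded-step-specific choices apply there,
and only there: the step size is 0.003 rather than 0.001 (0.001 passes
the same bar by roughly 400 steps; 0.01 oscillates), and the lr is held
constant, because the plateau rule misfires on a 200-step overfit — the
validation dice dips below its epoch-1 value during the early
transient, every epoch counts as stale, and the lr collapses by 2⁻⁵
before learning takes off. This is a learnability check of the
architecture, not a performance claim.

## Augmentation policy

Each training image expands into exactly 38 variants: 36 rotations at
10° steps (0°–350°, identity included) and contrast rescalings ×0.9 and
×1.1 of the unrotated image. The published policy states the two
transform families and the factor 38; this decomposition is the minimal
one consistent with both. Rotation uses bilinear interpolation for
images and nearest-neighbour for masks (re-binarised), fills with black
(the fundus border colour), and is an exact index permutation at
multiples of 90°. Contrast maps each channel to mean + factor·(v −
mean) with the mean taken over FOV pixels, then clips to [0,1] —
"contrast modification by a scalar factor" read as linear scaling about
the mean; the implementation is isolated so it can be swapped.

## Evaluation

Confusion counts are tallied inside the FOV when an FOV mask exists
(the DRIVE convention; togglable). Sensitivity, specificity, accuracy
and F1 follow their standard definitions; the AUC reported alongside
them is the closed form 1 − ½(FPR + FNR) at the fixed threshold, which
is algebraically (Se + Sp)/2 — balanced accuracy, not a ROC sweep. A
conventional trapezoidal ROC-AUC over the probability map is provided
separately (`roc_auc_sweep`) so the two are never conflated. Predicted
probabilities binarise at a strict > 0.5 (ties to background). Dataset
summaries are unweighted means of per-image metrics, with undefined
(NaN) entries excluded; pooled-pixel aggregation is available as an
option. Error overlays colour TP green, FP red, FN blue, TN black.

## Synthetic data

The generator emulates what the pipeline needs from a fundus dataset: a
circular FOV disc on black, vessel trees grown as biased random walks
from near the disc centre with probabilistic bifurcation and width
tapering from ~8 px trunks to 1 px capillaries, a radial reddish
background gradient, vessels darkened by a contrast factor
(default 0.35), and Gaussian noise (default sd 0.02). At the default
256 px the vessel fraction falls in 0.02–0.20 across seeds, matching
real fundus annotations' order of magnitude. Everything derives from
one seed; sample i of a dataset uses seed + i.

What the synthetic data does **not** emulate: optic disc and macula
appearance, lesions and exudates, inter-image illumination variation,
JPEG artefacts, and annotation noise. Passing tests on this data
demonstrates that the implementation is correct and the architecture
can learn vessel-like structure — not that it reaches any particular
accuracy on DRIVE/STARE/CHASE_DB1/HRF, which would require the real
images and longer training.

## Numerical choices and degenerate inputs

- Mask binarisation threshold for file input: > 0.5 of full scale
  (absorbs JPEG artefacts in nominally binary annotations); PPM/PGM
  rasters decoded to wide integer types scale by 255 or 65535,
  whichever covers the data.
- Resizing: bilinear for images, nearest-neighbour + re-binarise for
  masks; identity resizes are bit-exact short-circuits; network input
  sides must be divisible by 4 so the two poolings invert exactly.
- Metrics with empty denominators return NaN and are excluded (and
  counted) in dataset means, never coerced to 0.
- Max-pool gradient routes to the first maximal element of each window.
- Zero-weight networks output exactly uniform probabilities (softmax of
  equal logits), used as a propagation oracle in tests.
- Problem sizes in the test suite (64–128 px images, 2–4 image
  datasets, ≤200 optimiser steps) are chosen as the smallest sizes that
  exercise every code path meaningfully on a single CPU.

## Known limitations

Single-image batches make batch-norm statistics noisy; no attention
mechanism or multi-class head; training at 512×512 on large datasets is
CPU-bound and slow compared with GPU frameworks; leave-one-out training
orchestration is provided by `make_splits` but the CLI runs one split
per invocation.
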