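# Methods

## Problem and scope

Polyethylene mulch left in cotton fields fragments under straw crushing,
ploughing and seed-bed preparation, so by the pre-sowing stage the soil
surface carries many small, bright, irregular film pieces. `rfilm`
estimates the areal pollution they cause from nadir UAV RGB imagery in
three stages: (1) per-pixel semantic segmentation of film vs. background
with a slimmed U-shaped network, (2) per-pixel evaluation of the
segmentation against ground truth, and (3) conversion of predicted masks
into the film coverage rate, validated by regression against true
coverage. Because no public imagery of this kind exists, the package ships
a synthetic scene generator that reproduces the statistical structure of
such surveys and provides pixel-exact ground truth.

## Segmentation model

The network is an encoder–decoder with three 2×2 max-poolings. Each
encoder stage is an *inception block*: two parallel branches — a 1×1
convolution, and a 1×1 convolution followed by a 3×3 convolution — are
channel-concatenated and reduced by a trailing 1×1 convolution; every
convolution is same-padded and ReLU-activated. The parallel receptive
fields fuse features at two scales, which suits film fragments whose
apparent size varies with flight height. The decoder mirrors the encoder
with 2×2 stride-2 transposed convolutions, skip concatenation with the
same-resolution encoder map, and a *single* 3×3 convolution per stage
(half the classic U-Net's two). A 1×1 head produces 2-class logits;
probabilities come from a softmax, and mask decoding takes the per-pixel
argmax with ties broken toward background, so an uninformative model never
hallucinates film.

Default widths are encoder (64, 128, 256) with a 512-channel bottleneck
and branch width equal to half the block's output width. These were chosen
by exact parameter counting so the default model has 3,543,586 trainable
parameters — about 11% of the 31,031,810 of a reference classic U-Net
(four poolings, base width 64, two 3×3 convolutions per stage), keeping
the "order of magnitude smaller than U-Net" design point. Three poolings
(not four or five) were chosen so the working resolutions 1200×600 and
1024×512 divide evenly; odd-sized inputs at inference are reflect-padded
to the next multiple of 8 and the output cropped back.

The layers are implemented directly in NumPy (NHWC float32) with explicit
forward/backward passes. Convolutions run as im2col matrix products; the
data gradient of a same-padded stride-1 convolution is computed as a
convolution with the spatially flipped, channel-transposed kernel, and the
2×2 stride-2 pooling/up-sampling operators reduce to reshapes because
their windows do not overlap. Analytic gradients are verified against
central finite differences in float64 in the test suite. Initialisation
is He-normal (fan-in), appropriate for ReLU networks.

## Training recipe

Loss is per-pixel sparse categorical cross-entropy on integer {0,1}
labels; the optimiser is Adam with initial learning rate 0.001 and batch
size 6; training runs a fixed number of epochs (55 in the full-scale
recipe) with no early stopping and no learning-rate schedule. Each epoch
consumes exactly one freshly augmented variant of every training pair —
480 training images over 55 epochs stream 26,400 samples — and is followed
by an un-augmented, full-resolution evaluation of the validation set.
Weights are checkpointed only when the validation metric improves; the
default criterion is minimum validation loss, switchable to maximum
validation pixel accuracy (the selection criterion is a genuinely open
choice; loss was preferred as the smoother signal).

Augmentation applies exactly four operations: a uniformly positioned crop
(1024×512 out of 1200×600 by default), independent left–right and up–down
flips with probability 0.5 each, and a multiplicative brightness factor.
The brightness magnitude is unspecified territory; U(0.8, 1.2) was chosen
as a mild symmetric default, applied to the image only with clipping to
[0, 255]. Crops and flips are applied identically to image and mask, so
the {0,1} mask alphabet and the pairing are invariants.

## Evaluation metrics

With film as the positive class, the panel is accuracy, precision, recall,
F1, and a two-class IOU defined as the mean of the film-class and
background-class Jaccard indices:

    IOU = ½·( TP/(TP+FP+FN) + TN/(TN+FN+FP) ).

"MIOU" over a test set defaults to the arithmetic mean of per-image IOU
(the reading most consistent with a mean over a test set); the pooled
variant — IOU of the summed confusion counts — is always reported
alongside. Zero-denominator conventions: a class absent from both masks
contributes a vacuously perfect term (1.0); precision is 1 when nothing
was predicted positive and nothing was missed, else 0 when TP+FP = 0, and
recall symmetrically. Rationale: vacuously perfect agreement should not be
penalised, and an all-background test image should not poison a batch
average.

## Pollution index and regression validation

The coverage rate L = 100 · (film pixels)/(M·N) is computed in exact
integer arithmetic before the single final division. Predicted (L1) vs.
true (L2) coverage over a test set is summarised by a *prediction*
R² = 1 − Σ(L2−L1)²/Σ(L2−mean L2)² — computed on raw residuals, not on a
fitted line, so it can be negative for poor predictors — together with
RMSE, the mean relative error MRE = mean(|L1−L2|/L2)·100%, and the slope
and intercept of an ordinary least-squares fit of L1 on L2. Images with
zero true coverage are excluded from the MRE (relative error is undefined
there) with a logged warning and a reported exclusion count, rather than
failing the whole report. Pollution-degree class boundaries are
deliberately user-configurable thresholds, not built-in constants: no
standard boundary set exists for coverage-rate-based grading.

## Synthetic scene generator

The generator emulates the features of pre-sowing cotton-field imagery
that drive segmentation difficulty, not photorealism:

* **Soil background** — a mean soil tone with low-frequency tonal drift
  (amplitude 12 intensity units), per-pixel grain (σ = 5), bright
  yellow straw line segments, and elliptical clods darker or lighter than
  the surrounding soil. Optional dark drip-irrigation belts are off by
  default.
* **Weather** — sunny scenes get a 1.25× global contrast stretch and
  near-white (235–255) specular highlights on about half the clods: the
  classic false-positive confuser. Cloudy scenes are flatly lit.
* **Film fragments** — a Poisson(8) number of radially perturbed,
  randomly oriented elliptical polygons with log-uniform areas in
  [40, 4000] px² at the 5 m reference height, composited with brightness
  190–255 and partial alpha 0.55–0.95 so soil texture bleeds through,
  plus per-fragment specular streaks (crumpled film catching light).
* **Flight height** — fragment areas scale by (5/height)², emulating the
  growth of ground sampling distance, and the rendered image (never the
  mask) is blurred with Gaussian σ = 0.4·(height/5): visibly but not
  destructively softened at 9 m.

The mask is the exact union of rasterised fragment supports, so
realised coverage equals the pixel-count ratio exactly, and the
height/weather axes give the generator a built-in, monotone difficulty
ordering. When a target coverage is requested, fragments are added
(sized toward the deficit but respecting the configured size
distribution) or removed until realised coverage is within ±0.5
percentage points, with a hard cap of 200 attempts before an error that
names the closest achieved value.

What the generator does *not* model: orthomosaicking and radiometric
calibration, perspective and terrain relief, rotor-downwash displacement
of fragments, and the long-tailed fragment-shape statistics of real
tillage. Passing tests on synthetic scenes therefore demonstrate that the
pipeline's machinery is correct and that its difficulty orderings respond
to the modelled degradations; they do not certify field accuracy on real
imagery, for which no public reference data exist.

## Smoke-experiment problem sizes

The full-scale recipe (600 images at 1200×600, 55 epochs, 3.5 M
parameters) is the production configuration. The package's end-to-end
verification instead uses a deliberately small but complete experiment:
80 easy scenes (high-contrast film: brightness 235–255, alpha 0.85–1.0)
at 256×256 split 64/8/8, a reduced-width model (encoder (8, 16, 32),
bottleneck 64; ~56 k parameters), 192×192 training crops, and 15 epochs.
These sizes were chosen as the smallest at which segmentation quality
(mean per-image MIOU ≥ 0.80), coverage regression (R² ≥ 0.9), and the
weather/height difficulty orderings are all clearly resolved; the
stratified evaluation uses 48 scenes (8 per weather × height cell) so
each stratum average is reasonably stable.

## Numerical and degenerate-input choices

* Mask resampling is nearest-neighbour always; bilinear would create
  non-binary labels.
* Dataset splits use sizes round(n·ratio) for validation and test with
  the remainder assigned to train (600 → 480/60/60, 10 → 8/1/1), over a
  seeded shuffle; split membership recorded in a manifest takes
  precedence when present.
* Training aborts with a diagnostic naming the epoch if the loss becomes
  non-finite.
* With learning rate 0 the optimiser provably leaves weights unchanged
  (used as a sanity test).
* All randomness flows from explicit integer seeds through
  `numpy.random.Generator`; identical (config, seed) reproduces images,
  masks, manifests and training runs bit-exactly.

## Known limitations

* The NumPy training loop is single-threaded BLAS-bound; it is meant for
  the reduced smoke configuration and modest datasets, not for training
  the full 3.5 M-parameter model at 1200×600 scale.
* The generator's fragment-size and coverage distributions are plausible
  but unvalidated against real fields (no public measurements exist to
  calibrate them).
* MIOU stratification contrasts on small strata (a handful of images per
  cell) are noisy; orderings should be read from ≥8 images per cell.
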