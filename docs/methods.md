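# Methods

## Problem and approach

A tongue crack is a dark, zigzag strip of varying width on the tongue
surface.  Detecting and delineating cracks is difficult for standard
semantic segmentation because cracks are thin, their colour is close to
the surrounding coating, and clinical datasets are small (hundreds of
images).  The package follows the two-stage *segmentation-based* design
used for industrial surface-defect detection: a fully convolutional
segmentation network produces a coarse per-pixel crack score, and a small
decision network classifies the whole image from the segmentation output
and features.  Splitting the problem this way lets the pixel stage be
trained densely (every cell of every image is a labelled example) while
the image-level classifier, which sees far fewer labels, only fine-tunes a
small head — a good fit for small datasets.

## Architecture

Segmentation network (input H×W×3, H and W divisible by 8; inputs that
are not are rejected rather than silently padded):

| block | layers | output |
|---|---|---|
| 1 | 2 × (5×5 conv, 32 ch) + 2×2 max-pool | H/2 × W/2 × 32 |
| 2 | 3 × (5×5 conv, 64 ch) + pool | H/4 × W/4 × 64 |
| 3 | 4 × (5×5 conv, 64 ch) + pool | H/8 × W/8 × 64 |
| wide | 1 × (15×15 conv, 1024 ch) | H/8 × W/8 × 1024 |
| head | 1 × (1×1 conv, 1 ch) | H/8 × W/8 logit map |

Eleven convolutions, three poolings, total downsampling 8.  All
convolutions are stride-1 and same-padded; every one except the head is
followed by batch normalisation (momentum 0.9, eps 1e-5; evaluation mode
uses running statistics) and ReLU.  No dropout: the weight-shared
convolutions are regularisation enough at these data sizes.  The wide
15×15 layer supplies the receptive field needed to tell a crack from a
papilla dot or a contour edge by context rather than by local darkness.

Decision network: the feature volume and logit map are concatenated
(1025 channels), then pool → 5×5/8 → pool → 5×5/16 → pool → 5×5/32 (each
conv followed by ReLU), then global max- and average-pooling of the 32
trunk channels plus global max- and average-pooling of the logit map form
a 66-vector feeding a fully connected layer with a single output logit.

**No batch normalisation in the decision trunk.**  This is deliberate:
with the class-alternating sampler and batch size 2, every decision-stage
batch is single-class, so batch statistics would encode the label itself
during training.  A decision net trained that way scores near-perfectly
in train mode and *below chance* in evaluation mode (we measured held-out
accuracy 0.22 with BN vs 1.00 without, same seed).  The segmentation net
keeps BN because its per-cell targets are not batch-constant, which
removes the shortcut.

Initialisation is He-normal for convolution and (1/n)-scaled normal for
FC weights, BN scale 1 / shift 0, and the 1×1 head bias starts at −2
(sigmoid ≈ 0.12, a reasonable prior for the fraction of crack cells in a
cracked crop), all drawn deterministically from one integer seed.

## Training

Two phases, both plain SGD — learning rate 0.005, no momentum, no
schedule, no weight decay, batch size 2 — with the loss multiplied by a
constant 0.1.  That multiplier is exposed separately (`loss_weight`)
rather than folded into the learning rate so the published pairing
"learning rate 0.005, cross-entropy factor 0.1" can be stated as such;
mathematically it only rescales the step.  One iteration is one optimizer
step on one batch; the class-alternating scheduler indexes batches: even
iterations draw cracked images, odd iterations non-cracked ones, so the
two classes are visited at a constant rate regardless of imbalance.

Phase 1 trains the segmentation network with mean per-cell binary
cross-entropy between the sigmoid of the logit map and the ground-truth
mask max-pooled by 8 (a cell is positive iff any of its 64 pixels is
crack).  An optional per-pixel MSE mode on the probability map is
provided; a mention of bounding-box MSE regression in the source
literature has no corresponding component in this mask-output
architecture and is not implemented.  Phase 2 trains the decision network
with image-level binary cross-entropy while the segmentation weights stay
frozen — they are bit-identical before and after, which also allows the
segmentation outputs to be computed once per sample (evaluation mode) and
cached.

## Synthetic data

Real cracked-tongue images are private, so the generator emulates the
structure of the task:

* **Cracks**: 1–3 random polylines of 4–10 vertices with alternating-sign
  turns (zigzag); each vertex carries a half-width drawn from
  `width_range` (default 1–4 px) interpolated linearly along segments, so
  width changes along a crack.  The mask is the exact rasterised strip.
* **Background**: 2–4 random 2-D cosines (amplitude 5–12 gray levels)
  plus Gaussian speckle (σ = 3) around gray 150, mapped to a reddish RGB
  palette.
* **Contrast**: crack pixels are darkened by `contrast_gap` gray levels
  (default 25 — low, as in real images; the scaled-down learning
  experiment uses 60).
* **Distractors**: bright papillae dots (radius 0.8–2 px) and a darker
  elliptical contour ring near the border are drawn on the image but
  *excluded from the mask*, so a model must learn to reject exactly the
  structures that fool local-threshold baselines.

All randomness flows from `numpy.random.default_rng([config.seed, sample
seed])`; identical inputs reproduce byte-identical samples.  What the
generator does **not** model: real tongue colour classes and coating,
saliva glare, shape variability of the tongue outline, annotation noise.
Passing tests on synthetic data therefore demonstrate that the pipeline
is implemented correctly and can learn this class of geometry at low
contrast — not clinical-grade performance.

## Post-processing and evaluation

The logit map is binarised (sigmoid, strict `>` threshold, default 0.5),
upsampled 8× nearest-neighbour, eroded once with a full 3×3 rectangular
structuring element, and thinned to a one-pixel skeleton.  Morphology
runs at full resolution *after* upsampling: a 3×3 erosion on the 50×50
map would destroy one-cell cracks.  Thinning is Guo–Hall two-subiteration
thinning (`skimage.morphology.thin`): it is anti-extensive, idempotent
and preserves 8-connected components.  One caveat: "the skeleton contains
no 2×2 block" is not a universal property of connectivity-preserving
thinning — around holes and at rare branch junctions a 2×2 block can be
undeletable (Zhang–Suen is strictly worse here).  On the mask families
this pipeline produces (upsampled cell blocks, crack strips) we observe
no violations across hundreds of seeds, and the tests check the property
on those families.

Area-based quantities (confusion-matrix metrics, FCI) use the eroded
mask, not the skeleton, whose area is degenerate by construction.
Segmentation metrics accumulate one confusion matrix over the evaluated
set (micro-averaging) with rows = ground truth; per-class pixel accuracy
is the recall-like reading `CPA_i = P_ii / Σ_j P_ij` — the summand of the
MPA formula and the only reading that yields a crack-specific value.
Classes absent from both ground truth and prediction are excluded from
means; decision metrics with a zero denominator return NaN with a
warning.

`evaluate_model` computes pixel metrics at full upsampled resolution.
The end-to-end learning experiment in the acceptance tests instead scores
crack IoU at the logit map's native 1/8 resolution (thresholded cells vs
max-pooled mask): at full resolution even a *perfect* cell-level
predictor cannot exceed crack IoU ≈ 0.39 against a 2–8 px wide strip,
because an 8×8 block is the finest unit the architecture can emit, so the
cell level is where segmentation quality is actually measurable.

## Crack indices

`FCI = k_v · S_t / S_f` with `k_v = 10`: crack-pixel count over non-crack
pixel count, over the whole (pre-cropped) tongue patch by default, or an
optional region mask.  `FDI = k_d · (G_f / G_t − 1)` with `k_d = 2`:
luma (0.299 R + 0.587 G + 0.114 B) ratio of non-crack to crack area,
positive when cracks are darker.  Both are defined as exactly 0 for an
empty crack mask (FDI's ratio is undefined there; 0 is the published
convention for a crack-free tongue).

## Live-wire annotation core

Ground truth is produced from a few anchor clicks: `cost(p) = 1 −
g(p)/g_max + 0.01` with `g` the central-difference gradient magnitude, so
the strongest edge costs 0.01 and flat areas cost ~1.01; Dijkstra finds
the 8-connected path minimising the sum of entered-pixel costs (diagonal
steps × √2, start pixel free, deterministic tie-break by neighbour scan
order).  Consecutive anchor paths are concatenated into a closed chain
and filled by the even-odd scanline rule with boundary pixels included.
The cost formula is a package choice: the original annotation tool's
model is unpublished, only its "magnetic" shortest-path behaviour is.

## Problem sizes and numerical choices

Everything runs in float32 (tests of gradients use float64); convolution
is channels-last im2col + BLAS sgemm, and gradients were verified against
naive-loop convolution and central finite differences.  Deterministic
given seeds: no threads, fixed reduction order.

The end-to-end experiment in the test suite trains on 64 synthetic crops
of **64×64** (32 cracked / 32 not, contrast gap 60, seeds 0–2, 500 + 500
iterations, batch 2) and evaluates on 32 held-out crops — about 3 minutes
per seed on one CPU.  64×64 preserves the task geometry (cracks span the
crop; 8×8 logit cells) at a quarter of the cost of 128×128; observed
results are median held-out decision accuracy 0.97 and crack-cell IoU
0.53 across the three seeds.

Known limitations: no GPU path and no minibatch parallelism (batch 2 by
design); the synthetic domain gap noted above; crack *instances* are not
separated, so FCI aggregates all cracks in a crop; inputs must be
multiples of 8 on each side.
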