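# Methods

This note documents the models and procedures implemented in `wildtrap`,
the choices made where the design was genuinely open, and what the
synthetic-data experiments do and do not demonstrate.

## Problem setting

Camera traps produce day/night imagery with heavy background clutter;
detection accuracy degrades sharply for nocturnal, rainy scenes, and
false positives arise from background structures (earth mounds, stumps,
leaf piles) that resemble animals.  The package implements an anchor-free
one-stage detector for this regime: a small CSPDarknet/PAFPN/decoupled-head
network (depth multiple 0.33, width multiple 0.50) extended with three
components — pooling-token-mixer refinement blocks, a stackable dynamic
detection head, and the Focal-IoU regression loss.

## Baseline detector

The baseline follows the standard small-variant design of the YOLOX family:

* **Backbone** — CSPDarknet with a Focus (space-to-depth) stem, SiLU
  activations, batch normalization, and an SPP bottleneck (5/9/13 stride-1
  max pools) in the last stage; three output levels at strides 8/16/32 with
  128/256/512 channels at width 0.50.
* **Neck** — PAFPN: top-down feature fusion followed by bottom-up path
  aggregation, all CSP blocks with `shortcut=False`.
* **Head** — decoupled per-level head: 1×1 stem to 128 channels, two 3×3
  convolution towers, then 1×1 predictors for class logits, four box
  regression values, and an objectness logit.  Classification and
  objectness priors are initialized to a 1% foreground probability.
* **Decode** — per location, `center = (grid + delta) * stride`,
  `size = exp(raw) * stride`; score = `sigmoid(obj) * sigmoid(cls)`;
  class-wise greedy NMS (IoU 0.65) after a 0.01 confidence threshold.
  Boxes are `(x_min, y_min, x_max, y_max)` in 0-based continuous pixel
  coordinates, origin top-left (COCO convention).

## Refinement blocks (pooling token mixer)

Each of the three backbone outputs passes through one shape-preserving
local–global block: an n×n local convolution (n = 3), a 1×1 projection to a
transformer width `d`, an unfold into 2×2 patch tokens, one MetaFormer
layer, a fold, a 1×1 projection back, concatenation with the block input,
and an n×n fusion convolution (2c → c).  The MetaFormer layer replaces
multi-head self-attention with the parameter-free PoolFormer mixer

    mixer(x) = AvgPool3x3(x) − x ,

stride 1, same padding, with border averages over in-bounds elements only
(`count_include_pad = False`).  The mixer operates on the folded 2-D map —
the natural reading of a *spatial* pooling operator — while unfold/fold are
retained around the layer for structural fidelity to the MobileViT layout;
token normalization is layer normalization over channels, and the MLP is
2-layer with ratio 4.  A single transformer layer is used (depth 1).

Two placements are provided and use identical blocks (hence identical
parameter counts): `embedded` (blocks interleaved after the last three
backbone stages) and `after_backbone` (blocks between backbone and neck,
the better-performing arrangement and the default).

**Choice of `d`.**  The published accounting for this component is
+13.4 M parameters / +24.4 G FLOPs at 640×640, but the transformer width,
patch size and MLP ratio are not published.  With patch 2 and MLP ratio 4
fixed at their conventional values, `d ≈ 1.1 c` reproduces both printed
numbers simultaneously; the default is `d = round(1.104 c)` per level
(141/283/565), calibrated once against the printed budget and exposed in
the `refine:` config section.  `d = c` would give +12.7 M / +23.2 G.

## Dynamic head

The three neck outputs are projected (1×1 conv + BN) to a common width of
128 channels and bilinearly resized to the middle (stride-16) level,
forming a level × space × channel tensor.  Each block applies:

* **Scale-aware attention** — per level, a scalar gate
  `hard_sigmoid(linear(mean(F)))` with `hard_sigmoid(x) = clamp((x+1)/2, 0, 1)`;
  the linear map is zero-initialized (gate 0.5).
* **Spatial-aware attention** — a modulated 3×3 deformable aggregation with
  K = 9 sampling points; offsets and sigmoid-bounded modulation masks come
  from a conv branch on the middle level and are shared across levels, and
  the aggregation weights are shared across levels.  The branch is
  zero-initialized, so training starts from the plain-convolution
  degenerate case (offsets 0, masks 0.5).
* **Task-aware attention** — per channel,
  `max(α¹ F_c + β¹, α² F_c + β²)`, the four coefficients produced by global
  pooling → two FC layers → hard-tanh normalization `clamp(x, −1, 1)`
  around the identity initializer (α¹, α², β¹, β²) = (1, 0, 0, 0).  The
  hard (clamped) normalization is used instead of a smooth shifted sigmoid
  so the initialization is exactly the identity and the coefficients are
  exactly bounded; a smooth sigmoid can satisfy neither exactly.

Blocks stack N times (default 2, the best-performing depth in the source
experiments); afterwards levels are resized back to their native spatial
sizes and projected back to their native channel widths, leaving the
decoupled head identical to the baseline.  FLOPs are affine in the stack
count; parameters are strictly increasing.

## Losses

The box-regression family is `L = 1 − IoU + R` with `R = 0` (IoU),
the enclosing-box penalty (GIoU), the normalized center distance (DIoU),
or DIoU plus the aspect-ratio term `αv` (CIoU).  The **Focal-IoU** loss is

    L_FocalIoU = IoU^γ · (1 − IoU),      γ = 0.5 (default),

i.e. the plain IoU loss re-weighted by overlap quality: it vanishes at
IoU = 0 (hopeless pairs are down-weighted rather than dominating the
gradient) and at IoU = 1, with its maximum `2·3^(−3/2) ≈ 0.3849` at
IoU = γ/(γ+1) = 1/3.  The penalty term is not composed with the focal
weight by default (the loss is listed separately from the penalized
variants), but `IoU^γ` can be combined with any variant through the config.
The focal *classification* loss `−α_t (1−p_t)^γ log p_t` is implemented
and config-selectable; the deployed classification/objectness losses
remain binary cross-entropy, per the baseline design.

Degenerate (zero-area) boxes yield IoU 0 with a warning, never NaN.  In
the differentiable focal-IoU path, `IoU^γ` uses a 1e-7 floor so the
gradient stays finite at zero overlap (the analytic value is 0 either way).

## Training

SimOTA dynamic assignment: candidate locations lie inside a ground-truth
box or within 2.5 strides of its center; the assignment cost is the joint
classification BCE plus 3·(−log IoU), with a large penalty for candidates
failing either prior; per object, the top-k lowest-cost candidates are
taken with k = clamp(Σ top-10 IoU, 1, #candidates), conflicts resolved by
minimum cost.  Losses follow the baseline normalization — each component
is a sum divided by the number of foreground assignments — with weights
5 (box), 1 (class), 1 (objectness).  Classification targets are one-hot
scaled by the current predicted-box IoU, so the ranking score
`sigmoid(obj)·sigmoid(cls)` learns to track box quality.

The reference schedule is 300 epochs of cosine annealing from lr 0.01 to
0.0001, momentum 0.9, with strong augmentation (mosaic, horizontal flip,
HSV jitter) during the first 285 epochs only.  Both SGD-with-momentum and
Adam are provided (the source description names both; SGD is the family
convention and the default).  Batch size 8 and weight decay 5e-4 are
package choices, not published values.  A single integer seed governs
splitting, initialization and augmentation and is recorded in every log.

## Evaluation

COCO-protocol mAP: per class and IoU threshold, detections are sorted by
score and greedily matched (each ground truth at most once, best IoU
first); average precision uses the precision envelope sampled at 101
recall points; mAP@0.5:0.95 averages thresholds 0.50:0.05:0.95.  Classes
with no ground truth are excluded from the mean (their AP is undefined in
the protocol).  The test-suite checks equivalence against an independent
brute-force implementation of the same protocol to 1e-6 on randomized
scenes.

## Architecture accounting

Parameters are trainable scalars.  FLOPs use the convention of the
profiling tools behind the published model tables: 2 FLOPs per
convolution/linear multiply-accumulate plus 4 FLOPs per normalization
output element; activations, pooling and resizing are free.  Under this
convention the 80-class base model measures 9.0 M / 26.8 G at 640×640
(the published base row reflects the COCO-pretrained configuration; the
nine-class variant measures 8.9 M / 26.7 G), the refined model 22.4 M /
51.2 G, and the refined + 2-stack dynamic-head model 23.0 M / 55.0 G.
The published 56.4 G for the last configuration is inconsistent with the
same source's per-stack increments (≈1.1 G per stack), which this build
matches; the discrepancy is documented rather than fitted.

## Synthetic data

The generator emulates the statistical failure modes of camera-trap
imagery rather than its photographic detail: multi-octave value-noise
backgrounds; nine classes of textured parametric sprites (ellipse body
plus per-class appendage lobes, hue and aspect fixed per class) with a
mildly imbalanced class distribution (weights ∝ 1/(1+0.15·class));
camouflage as a mix of sprite color toward the local background mean;
night as luminance ×(1−0.8·level), saturation ×(1−0.9·level) and
monochrome sensor noise (σ = 0.04·level); rain as `round(density·200)`
semi-transparent near-vertical streaks over a slight global blur.
Night/rain probabilities default to 0.3 each and objects to 1–3 per image.
Everything is deterministic per (config, index), and degradations never
move ground-truth boxes.

What passing tests show: the full pipeline — generation, assignment,
differentiation, decoding, evaluation — is self-consistent, and a reduced
detector (width 0.25, 256×256) can overfit 20 such scenes to train-set
mAP@0.5 ≥ 0.9 within 300 iterations (Adam, cosine 1e-3 → 1e-4 with a
15-iteration linear warmup, batch 8, weight decay and augmentation off —
the natural settings for a memorization check; problem sizes chosen so
the whole check runs on a single CPU).  What they do not show: generalization to real wildlife imagery, or
the published accuracy tables, which require the authors' private ~4000
image dataset and full-scale training.

## Numerical infrastructure

All layers run on a compact numpy autodiff engine inside the package
(im2col/GEMM convolutions with a col2im backward, composite batch/layer
norm, bilinear resize as separable interpolation matrices, modulated
deformable sampling with analytic offset gradients).  Every primitive's
gradient is verified against central finite differences in the test-suite.
Float32 is used throughout; training-path clamps: `exp` arguments for box
sizes to ±8, BCE computed in the stable `max(x,0) − xt + log(1+e^{−|x|})`
form.

## Known limitations

* Training at realistic scale (hundreds of epochs, large images) is out of
  reach of a CPU-only numpy engine; the package targets correctness and
  small-scale experiments.
* The nine-class calibration of the published parameter budget fixes `d`
  but cannot be verified against the authors' (unpublished) block
  hyperparameters.
* The evaluator handles no "crowd" regions and the generator renders no
  occlusion between animals.
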