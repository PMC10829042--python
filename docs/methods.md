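# Methods

## Problem and model

The task is binary semantic segmentation — sugarcane field vs
background — on 512×512 RGB tiles cropped from high-resolution
satellite scenes. The model is an encoder–decoder:

* **Encoder**: ResNet34 (stem 7×7/2 + BN + ReLU + 3×3/2 max-pool;
  stages of 3/4/6/3 basic blocks at 64/128/256/512 channels). Stages
  3–4 use stride 1 with dilations 2 and 4 instead of striding, giving
  output stride 8 — the conventional arrangement under a pyramid-pooling
  decoder, enlarging the receptive field at unchanged parameter count.
  The exact dilation rates are not fixed by the architecture's
  description anywhere authoritative; (2, 4) is the DeepLab-style
  default and is exposed in `BackboneSpec`.
* **D-scSE attention** after each stage and after the decoder
  concatenation. Spatial branch: 1×1 conv `W_k ∈ R^{C}` + sigmoid, a
  per-pixel gate. Channel branch: concatenated global average and max
  pooling (a 2C descriptor), ReLU, one fully connected layer
  `W ∈ R^{C×2C}`, sigmoid, a per-channel gate. The branch outputs are
  combined as `α·U_sSE + β·U_cSE` with trainable scalars initialised
  from `U(−√(6/n), √(6/n))`. The ReLU is applied to the pooled
  descriptor *before* the single FC layer — exactly as the gating
  formula `σ(Wδ(x))` reads — rather than between two FC layers as in
  classic cSE. Biases on the 1×1 conv and the FC layer are included but
  zero-initialised, so at initialisation the block computes the
  bias-free formulas exactly. `n` for the fusion init defaults to 2
  (the fusion sum has two inputs; bound √3) and is configurable, since
  nothing pins it.
* **Decoder**: four parallel average-pooling branches at grid sizes
  (1, 2, 3, 6) — the classic PSP setting, again a choice since only
  "unique kernel sizes" is prescribed — each reduced to C/4 = 128
  channels by a 1×1 conv + BN + ReLU and bilinearly upsampled;
  concatenated with the input map (1024 channels); D-scSE on that map;
  3×3 conv to 512 + BN + ReLU; 1×1 conv to 2 classes; bilinear ×8.
  Two-channel softmax logits rather than a single sigmoid channel keep
  the four-cell confusion semantics of the metrics exact.
* No auxiliary loss branch.

One D-scSE block at width C holds `2C² + 2C + 3` trainable parameters
(FC 2C²+C, spatial conv C+1, fusion 2). The five insertions of the
pinned configuration (C = 64, 128, 256, 512, 1024) cost 2,797,455
parameters in total, and the test suite asserts that the difference
between the full and attention-free models equals this closed form.

### Parameter totals vs published budgets

The pinned model counts 29.07 M trainable parameters and the
attention-free baseline 26.27 M. Published totals of 22.57 M / 21.44 M
for this architecture pair cannot be reproduced by *any* configuration
consistent with the description: a full ResNet34 encoder alone holds
21.28 M conv/BN parameters, so after adding the four C/4 pyramid
branches (0.26 M) the baseline already exceeds 21.44 M before a single
head channel, and the published pair differs by 1.13 M where the
closed-form attention budget is 2.80 M. The package therefore reports
its honestly counted totals; the decomposition (encoder + pyramid +
head + attention budget) is asserted term-by-term in the tests.
Published GFLOP figures are likewise tool- and convention-dependent;
the profiler states its convention (2 FLOPs per MAC, convolutions and
affine layers only, BN/activations ignored) inside every report and
the GFLOP number is reported, never asserted.

## Data pipeline

Scenes are cropped into non-overlapping 512×512 tiles on a row-major
grid (0-based, half-open boxes); partial tiles are refused. A
4096×4096 scene yields 64 tiles; 20 scenes yield 1280.

**Splitting** is per scene at 70/15/15. 70% of 64 is 44.8, so exact
per-scene allocation is impossible; each scene is rounded by largest
remainder with ties broken train > val > test (64 → 45/10/9), and a
deterministic correction pass then reassigns single tiles in seeded
scene order until the global totals equal the largest-remainder
rounding of fraction × total (20 × 64 → 896/192/192). Which tiles land
in which split is a seeded in-scene shuffle.

**Augmentation** applies, to every training tile and never to
validation or test tiles, five independent copies of the full
simultaneous transform chain: rotation ±45° and scaling 0.9–1.1 (one
bilinear resample; reflection padding for the image, background fill
and nearest-neighbour interpolation for the mask; quarter-turns at
unit scale take an exact array-rotation path), horizontal/vertical
flips, brightness/contrast ±0.2, HSV shifts 20/30/20 (8-bit scale),
Gaussian blur with kernel 3–7 (OpenCV kernel→sigma convention), and
Gaussian noise with variance 10–50 (8-bit scale). The ranges are
configuration, not contract: the dataset counts and bit-reproducibility
under a seed are what downstream stages rely on. Augmented records
store provenance only and re-render deterministically from the seed,
so a 5376-image training set needs no stored rasters.

Normalisation uses the per-channel mean/std of the original training
tiles (on the 0–1 scale), stored in every checkpoint.

## Synthetic scenes

The generator emulates winter-season sub-meter imagery of a
sugarcane-growing landscape: convex polygonal fields (convex hulls of
random ellipse samples) filled with a sinusoidal row texture (period
6–16 px, matching few-meter row spacing at sub-meter resolution) in
green tones over a heterogeneous background (bilinearly upsampled
coarse noise plus fine grain), with scene classes cycling through
river (a meandering dark ribbon), resident (bright rectangular roofs)
and farmland. Distractors are painted before the fields, so the mask
is exactly the union of field polygons. Fields are added until a
coverage target drawn from (0.30, 0.50) is met, with field size shrunk
as the target nears; scenes outside the range ±0.05 are regenerated
(bounded retries). Everything derives from the spec seed via stable
hashing, so scenes are byte-reproducible.

What the generator does *not* emulate: spectral mixing, shadows and
karst-terrain relief, phenological variation, sensor noise statistics,
or ambiguous boundaries between reaped and standing cane. Passing
tests therefore demonstrate the mechanics (equations, counts,
trainability, protocol), not field-ready accuracy on real imagery.

## Training

Two-class mean pixel cross-entropy (the loss is not otherwise pinned;
it is the simplest loss consistent with confusion-count evaluation),
AdamW with decoupled weight decay 1e-2 applied to all parameters, and
a triangular cyclical learning rate from 1e-4 to 1e-3, one cycle per
10 epochs (cycle length is configuration). Defaults are 100 epochs at
batch 16. Shuffling is seeded per epoch; the best checkpoint is chosen
by validation IoU; a non-finite loss raises a divergence error naming
the epoch. Checkpoints (npz) round-trip bit-exactly in eval mode.

## Evaluation

Per-pixel argmax over the two logits; TP/FP/FN/TN accumulated with
sugarcane as the positive class. The headline protocol is
micro-averaging (one pooled confusion table per split), under which
IoU = TP/(TP+FP+FN), Accuracy, Precision, Recall and
F1 = 2PR/(P+R) = 2·IoU/(1+IoU) are exact identities; the mean of
per-tile scores (macro) is reported alongside because published score
tables in this area often mix the two and the pair brackets the
ambiguity. Ratios with zero denominator and zero TP are defined as 0
and flagged in the report.

## Desk-scale configuration and problem sizes

CPU-scale work uses `ModelSpec.reduced()`: one block per stage, 1/8
channel widths (16/32/64/128), head 64, and output stride 4 (stage 2
keeps stride 1) — at 64-px tiles the stride-8 grid is too coarse to
resolve field boundaries, and stride 4 restores them at modest cost.
The trainability check trains this model on eight 64×64 tiles of one
synthetic farmland scene for at most 300 optimizer steps; it reaches
training IoU > 0.95 (typically by step ~100) and every α/β moves from
its initial draw. The dataset-arithmetic check runs the pipeline at
the full study scale (20 scenes of 4096²); inside the test suite the
augmented rasters are fully realised for one full-size scene (225
rasters, twice, checking the checksum is reproducible), while the
acceptance script renders all 4480.

## Numerical choices

float32 throughout; attention-oracle agreement tolerance 1e-6; BN eps
1e-5, momentum 0.1, batch statistics in training mode and frozen
running statistics in eval mode; bilinear resizing uses half-pixel
centers without corner alignment; adaptive pooling uses floor/ceil bin
edges so any grid size divides any input; min–max normalisation of
attention heat maps maps constant activations to all zeros;
He (fan-out) initialisation for convolutions and uniform ±1/√fan_in
for FC layers, all drawn from per-module seeds derived by stable
hashing of (global seed, module path).

## Known limitations

* Training the full 29 M-parameter model at 512² is possible but slow
  on CPU (~3 s per forward); the package targets desk-scale
  demonstrations and profiling of the full model, not full-scale
  training runs.
* The published parameter/GFLOP/memory table cannot be reconciled with
  the described architecture (see above); the profiler's numbers are
  self-consistent instead (memory = parameters × 4 bytes exactly).
* The synthetic corpus is deliberately simple; accuracy numbers
  obtained on it say nothing quantitative about real satellite scenes.
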