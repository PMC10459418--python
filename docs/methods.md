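# Methods

## The model

`tsidl` treats lookalike-drug classification as a routing problem. A global
("stage-1") classifier is adequate for most classes; its failures are
concentrated on small sets of mutually confusable classes that share
packaging and coarse appearance. The method makes those sets explicit and
hands them to specialists.

**Cross-validated confusion matrices.** Each class contributes a pool of 50
train+val images and a fixed test block of 22. The pool is partitioned into
five blocks of 10; fold *f* trains on the other 40 and validates on block
*f*. Summing the five per-fold validation confusion matrices gives the
validation CVCM with exact support 50 per class; evaluating every fold
model on the same fixed test block and summing gives the testing CVCM with
support 5 × 22 = 110. The matrices use rows = true class, columns =
predicted class, so TP_i is the diagonal, FN_i the off-diagonal row sum,
FP_i the off-diagonal column sum.

**Grouping.** On the validation CVCM: flag class *i* when TP_i ≤ 48
(absolute mode, meaningful for support 50; relative mode uses
⌊0.96 · support_i⌋ for other designs); collect partners *j ≠ i* with
N_ij ≥ 1 from the flagged class's row only (its miss destinations — column
scanning exists behind an option but is off by default); union flagged
classes and same-package partners into one SD list per package class.
Cross-package partners are excluded (they are package-level errors, not
lookalike errors) and logged; an SD list left with a single member dissolves
into the residual, logged. Lists of ≥ 2 members become SG1..SGN ordered
lexicographically by package class. The output always partitions the label
set — this is validated on construction. A connected-components mode can
split a package's union into confusion-connected subsets; it is off by
default because the per-package union is the canonical behaviour.

**Region-of-interest cropping.** Candidate windows are the centred halving
ladder sides ⌊N/2^k⌋, k = 0..3. Windows are 0-based and half-open with
centre ⌊N/2⌋, copied without resampling, and never padded — a window larger
than the frame is an error. The choice of the optimal side per group is an
expert judgement in the field; here it is either (a) a manual configuration
mapping group → side, taking precedence when present, or (b) an automated
proxy: crop the group's own training/validation images at every candidate,
fit a quick multinomial-logistic classifier on the downscaled pixels, keep
the side with the best validation accuracy, break ties toward the larger
side (the conservative choice: more context). Crops are applied *before*
the backbone input resize — that ordering is the entire mechanism, since it
magnifies the central region relative to the input resolution.

**Stage 2 and inference.** Each group (and the residual) gets a dedicated
classifier over exactly its labels, trained on cropped (residual: full-
frame) images. Deployment inference uses a single final stage-1 model
trained on a seeded 40/10 re-split of the whole pool — the five fold models
exist only to produce CVCMs; their job ends at grouping. The routed group is
determined by the stage-1 argmax label alone; there is no abstention or
score threshold. Consequently a stage-1 routing error is irrecoverable:
stage 2 can only answer within the routed group. This is asserted in tests
as a documented contract, not patched over.

## Backbones

The full single-stage CNN is an AlexNet-shaped stack (5 conv + 3 dense,
227-pixel inputs, 96/256/384/384/256 maps, Fc6/Fc7 at 4096) recorded as a
declarative layer table; shape inference applies
side' = ⌊(side + 2·pad − kernel)/stride⌋ + 1 layerwise and reproduces the
table's printed sizes (55, 27, 27, 13, 13, 13, 13, 6 from 227).

Training runs on a compact numpy engine written for this package: im2col
convolution, max pooling, dense layers, ReLU, softmax cross-entropy, and
minibatch SGD with momentum (coefficient 0.9 — conventional, configurable;
He-style initialisation). Gradients are verified against central
differences in the test suite. All randomness flows through one seeded
generator, so identical (data, spec, config, seed) gives identical
parameters, curves and predictions. The desk-scale backbone (`tiny_spec`)
is three stride-2 convolutions (8/16/32 maps) and a softmax head on
32-pixel inputs. Validation runs after every epoch and the kept checkpoint
is the earliest epoch attaining the maximum validation accuracy. An
optional iteration cap complements the epoch cap; the epoch cap is the
default stopping rule.

Defaults of `TrainConfig` (learning rate 1e-4, batch 32, 100 epochs) mirror
the reference protocol for a pretrained AlexNet-scale network.
`desk_train_config` (learning rate 0.02, 45 epochs) is the from-scratch
setting for the tiny backbone: chosen during design so that residual
(visually distinct) classes converge to ≥ 49/50 validation TP on the
benchmark, leaving headroom below the 48 threshold for genuinely confusable
classes. Images are bilinearly resized (anti-aliased when downscaling) to
the backbone input side after any crop.

## The synthetic generator

The generator emulates the capture protocol of the motivating study — nine
camera directions (3 × 3 tilt/pitch grid of −20°/0°/+20°) times eight 45°
in-plane rotations, 72 images per class, split 40/10/22 — by rendering
rather than photographing. Each package type contributes a silhouette shape
and base colour; each class a coarse appearance of three coloured label
blocks; each class additionally a unique 5 × 5 low-contrast imprint glyph
in the frame centre. Classes inside a planted group share the *same* coarse
appearance, so the imprint is their only discriminative signal. Pose is an
affine warp (rotation plus cos-foreshortening and a small shift for tilt),
followed by ±8 % illumination jitter and additive Gaussian noise. Rendering
is pixel-deterministic per (seed, package, class, pose).

This construction makes cropping provably useful: downscaling a full
64-pixel frame to the 32-pixel input leaves the 10-pixel imprint ~5 blurred
pixels at contrast 0.12 under noise 0.06, while a 16-pixel centred crop
resized to 32 renders it at ~20 pixels. The property "same-group pixel
distance is larger after crop+resize than at full frame" is asserted
numerically in the tests.

What the generator does **not** emulate: real optics (shadows, reflections,
specular glare), texture and print detail, class imbalance, label noise, or
out-of-catalogue items. Passing tests therefore show the pipeline's
machinery is correct and that the method helps when lookalikes differ in a
small central region; they do not certify accuracy on photographic data.

**The desk-scale benchmark** (`benchmark_params`): 3 package types × 4
classes, planted groups of sizes 3 (ampoules) and 2 (bottles), 64-pixel
frames, imprint side 10, contrast 0.12, noise 0.06. Sizes were chosen so a
full 5-seed recovery study plus a 3-seed paired improvement study runs in a
few CPU-minutes; the split and support structure (72 images, 40/10/22,
validation support 50) is kept identical to the full-scale protocol.

## Numerical and design choices

- Zero-division in macro metrics: an undefined per-class precision (never
  predicted) or recall (zero support) contributes 0 to the macro average,
  with a warning — the conservative convention; well-formed experiments
  never hit it.
- Labels are ordered lexicographically unless a manifest dictates
  otherwise; serialized artifacts always carry the label order.
- Confusion-matrix TSVs round-trip bit-exactly; metric reports carry full
  double precision (display rounding is the caller's concern).
- Grouping thresholds are absolute counts by default (48-of-50); the
  relative mode exists because the absolute threshold is meaningless for
  other supports.
- The floor convention for odd crop/pyramid sizes (centre ⌊N/2⌋, sides
  ⌊N/2^k⌋) is used consistently; crop composition is exact on even sides.
- Manifest validation rejects duplicate paths and any drug mapped to two
  package types.

## Known limitations

- The numpy engine is CPU-bound and single-threaded beyond BLAS; training
  the full 227-pixel architecture with it is possible but impractical —
  the engine exists to make the pipeline executable and deterministic at
  desk scale, and the pipeline is backbone-agnostic by design.
- Pretrained initialisation is exposed as a flag but no pretrained weights
  ship with the package (they are an external artifact); synthetic
  experiments use seeded random initialisation.
- The automated ROI proxy ranks candidate crops with a linear model, which
  can underrate a crop whose benefit only a nonlinear model sees; the
  manual configuration path takes precedence where expert knowledge exists.
- Two-stage inference cost is roughly twice single-stage; no latency
  optimisation is attempted.
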