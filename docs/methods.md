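# Methods

## Problem and pipeline

Frog-eye leaf spot (caused by *Cercospora* fungi) produces small round
lesions on apple leaves. Management decisions depend on disease *severity*,
defined here as the percentage of the leaf's area covered by lesions,

    L = 100 * S_disease / S_leaf   [percent],

with both areas measured as pixel counts on binary masks at a common
resolution. `S_leaf` includes the diseased portion of the leaf. Severity is
graded on five ordinal levels by half-open intervals with inclusive lower
bounds: level 1 `[0, 0.95)`, level 2 `[0.95, 1.50)`, level 3 `[1.50, 2.15)`,
level 4 `[2.15, 3.00)`, level 5 `[3.00, ∞)` percent.

Estimation is two-stage. Stage 1 (L-DPNet) segments the leaf from a
cluttered orchard background; stage 2 (D-UNet) segments lesions within the
predicted leaf. The inference path letterboxes the image to the stage-1
input size, maps the predicted leaf mask back to the original resolution
(nearest-neighbour, so masks stay binary), zeroes non-leaf pixels, runs
stage 2 on the masked image letterboxed to its own input size, maps the
lesion mask back, and intersects it with the leaf mask. The intersection
guarantees `S_disease <= S_leaf`; areas are always counted at the original
image resolution. An image with an empty predicted leaf mask is reported as
*ungradable*, never silently graded level 1.

## Stage 1: L-DPNet

A pyramid-scene-parsing segmenter pruned for the two-class leaf task:

- **Backbone**: ResNet-bottleneck feature extractor at output stride 8
  (stages 3–4 dilated at rates 2 and 4). The full-size preset mirrors
  ResNet-50 (depths 3,4,6,3, expansion 4); a thin preset (depths 1,1,1,1,
  widths 8–16) trains on CPU for the synthetic-data tests.
- **Pruned pyramid pooling**: only the 1×1 (global) and 6×6 pooling bins are
  kept. Each branch adaptively average-pools, halves the backbone channels
  with a 1×1 convolution (BN+ReLU), and is bilinearly upsampled back to the
  feature-map size. The input map and all branches are concatenated (e.g.
  512 + 256 + 256 = 1024 channels for a 512-channel input) and fused by a
  3×3 convolution. Whether the input map joins the concatenation is not
  dictated by the pruning idea itself; we follow original pyramid-pooling
  practice and include it, and we add the 3×3 fusion convolution. Both
  choices are flagged as potential divergences from other implementations.
- **DP module**: a deformable 3×3 convolution attached to the 6×6 branch
  (configurable to 1×1, 6×6 or both for ablations), whose output is added
  element-wise back onto the branch. The addition operand is the branch
  *after* its channel-halving convolution so shapes match without extra
  projections.
- **Head**: 1×1 convolution to 2 classes; logits bilinearly upsampled to the
  input resolution. All bilinear resampling in the package uses the
  non-corner-aligned convention.

### Deformable convolution

Standard convolution samples a regular grid R of k² integer displacements:
`y(p0) = Σ_n w(p_n) x(p0 + p_n)`. The deformable variant adds a learned
fractional displacement per output position and kernel element:
`y(p0) = Σ_n w(p_n) x(p0 + p_n + Δp_n)`, reading fractional positions by
bilinear interpolation with the separable kernel `g(a,b) = max(0, 1-|a-b|)`,
so exactly the four integer neighbours of a sampling point contribute.
Positions outside the array contribute zero (consistent with zero-padded
convolution). Offsets are predicted by an auxiliary standard convolution
with 2k² output channels, zero-initialized so the layer *is* a standard
convolution at step 0; offsets are shared across channels (one offset
group). `frogeye.deformable_conv` is a plain-NumPy single-channel reference
of these equations; `frogeye.nn.DeformConv2d` is the batched multi-channel
trainable layer, tested against the reference and against a scalar
brute-force evaluator.

## Stage 2: D-UNet

A U-Net with a VGG16-style encoder: 5 blocks of (2,2,3,3,3) convolutions
with channels (64,128,256,512,512) — 13 convolutions — and 4 max-pools (the
5th pool and the classifier head dropped), emitting five skip levels at
strides 1,2,4,8,16. Batch normalization sits before every ReLU (toggleable
for the ablation). The decoder upsamples ×2 per stage — bilinear by
default, transposed convolution as the ablation variant — concatenates the
matching skip, then applies two 3×3 convolutions; channels are reduced by
the first convolution after concatenation. Bilinear decoding injects no
2×2-periodic (Nyquist) checkerboard component, which the test suite
verifies spectrally on an untrained network.

Training minimizes focal loss `FL(p_t) = -(1-p_t)^γ log(p_t)` with γ=2,
where `p_t` is the two-class softmax probability of the pixel's true class.
No class-balancing α term is used. Probabilities are clamped at 1e-8 before
the log. γ=0 recovers plain cross-entropy, which is the stage-1 loss.

## Training engine and hyperparameters

All layers (convolution via im2col, batch norm, max/adaptive-average
pooling, bilinear upsampling, transposed and deformable convolution, the
focal/cross-entropy head) are implemented in `frogeye.nn`, a small
float32 NumPy autodiff core, with Adam as the optimizer. The published
per-stage settings are the config defaults: input 473×473 (leaf) / 512×512
(lesion), 200 epochs, base learning rate 1e-4, batch 16 / 4, decay factor
0.1 / 0.96, 2 classes. The decay *shape* is not part of those settings; we
apply the leaf factor as step decay at 60% and 90% of the epochs and the
lesion factor per epoch (exponential), both config-exposed. The optimizer
choice (Adam) is ours. Letterbox padding pixels are excluded from the loss.

**Cascade training.** `pipeline.train_two_stage` trains the leaf stage
first and then trains the lesion stage on images masked by the *predicted*
leaf masks (targets intersected with the same masks). Training stage 2 on
ground-truth leaf masks leaves it facing a different input distribution at
deployment, where it sees stage 1's imperfect masks; on held-out synthetic
scenes this mismatch produced a systematic ~20–45% under-estimate of the
lesion ratio, which cascade training removes (bias ≈ 0.98 in the test
suite's end-to-end check). Per-stage training on annotated masks remains
available through `pipeline.train`.

## Evaluation

Pixel metrics come from the (k+1)×(k+1) confusion matrix `p_ij` (true i,
predicted j): per-class IoU `p_ii / (row_i + col_i − p_ii)` and per-class
accuracy `p_ii / row_i`, averaged over classes for mIoU and mPA; mPA is
algebraically the macro recall, and per-class IoU never exceeds per-class
accuracy. Counts are pooled over the whole evaluation set before ratios
("micro" pooling; per-image averaging is available behind the library
surface but is not the default). The combined two-stage report uses three
classes {background, leaf, disease}, with disease pixels excluded from the
leaf class; this relabeling is our choice and is noted as such. Grading
reports give per-true-level fraction correct (kept under the customary
"Precision(%)" column name, though it is a per-class recall), the
unweighted macro mean over the five levels, the same over levels 1–3, and
the 5×5 level confusion.

## Synthetic data

The generator emulates the single-leaf orchard scenes the pipeline
targets: one leaf — a rotated ellipse with sinusoidal boundary jitter,
optionally occluded up to 40% by a foreground blob — over one of six
background kinds (grass, trunk, shadow, healthy leaves, fruit, occluding
branch) rendered as low-frequency color textures. Frog-eye-like spots
(tan center, darker ring) are placed fully inside the visible leaf by
rejection sampling until the pixel ratio reaches a requested target within
±10% relative or one smallest-spot area, whichever is larger; radii are
floor-rounded so small targets are approached from below in
minimum-spot-area steps. A single integer seed drives a hierarchical
scene → leaf → lesion generator; identical specs and seed give
byte-identical output. Stored ratios/levels are always re-derived from the
emitted masks, so ground truth is exact by construction.

What the generator does **not** emulate: photometric realism, leaf venation
and 3-D pose, multi-leaf instance layouts, disease morphologies other than
round spots, annotation noise, and the resolution (4000×2672) of real
orchard photographs. Tests passing on synthetic scenes therefore
demonstrate the correctness of the pipeline's arithmetic, geometry and
trainability, not field-ready accuracy.

### Mosaic augmentation

The training-set augmentation collages random crops of four annotated
images in a 2×2 layout around a junction point jittered within ±20% of the
output size, applying the identical transform to image and masks. The
default policy appends exactly one collage per original (output size twice
the source), anchoring the original in quadrant 0 and drawing the other
three uniformly with replacement — the only policy consistent with exact
per-level doubling of the training counts under anchor attribution. The
manifest's `level` column of a collage is regraded from the collage's own
masks; `anchor_level` carries the anchor attribution used for per-level
accounting. Collages are generated once, offline. Sources smaller than
their quadrant are nearest-neighbour upscaled before cropping (logged);
per-quadrant provenance records allow bit-exact reconstruction.

## Numerical and procedural choices

- Pixel coordinates are 0-based, x right / y down; a pixel is inside a
  polygon iff its center is inside or on the boundary (shapely point
  queries); overlapping polygons union.
- Masks are {0,1} in memory, {0,255} in 8-bit PNG, with exact back-mapping;
  any other stored value is an error naming the value.
- The 8:1:1 split is stratified by level; per level, test gets
  round-half-up(n/10), validation round-half-down(n/10), training the rest,
  assigned by a seeded permutation. (An 8:1:1 split of 1,372 images is not
  integral; our rounding yields a deterministic 1,098/137/137 rather than
  chasing an unstated one.) Whether the original split was stratified is
  unknown; we stratify and say so.
- Precision/recall with an empty denominator return NaN, never a silent
  0 or 1; metric means skip classes with no pixels, with a logged note.
- Severity ratios use exact integer rationals before conversion to float;
  grade thresholds are overridable in config.
- Problem sizes in the test suite — thin models, 64×64 scenes for the
  8-image overfit checks, 96×96 scenes with 48 training images for the
  held-out grading check, 48×48 canvases for the 1,096-image augmentation
  count — were chosen so the whole suite trains from scratch on one CPU;
  they are stated here so results are interpreted at that scale.

## Known limitations

- The NumPy engine is CPU-only and single-threaded beyond BLAS; full-size
  (473/512) training is out of its intended scope, though full-size
  forward passes are exercised.
- Offset groups, modulated (v2) deformable convolution, and >2-class
  segmentation are not implemented.
- The severity grader assumes one leaf per image; multi-leaf scenes are
  graded by pooled area, which may not be agronomically meaningful.
- Checkpoints are NumPy `.npz` archives; no interoperability with other
  frameworks' weights is attempted (an optional load hook accepts any
  name-matched array dict).
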