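# Methods

`psyllidet` implements a complete desk-scale pipeline for detecting very
small orchard pests — citrus psyllids (average body length ≈ 2.5 mm, class 0)
and citrus fruit flies (≈ 5 mm, class 1) — in high-resolution RGB field
imagery. Psyllids are the sole insect vector of citrus Huanglongbing, so
early detection matters; the detection problem is hard because the insects
occupy only a handful of pixels, resemble branches/stems/withered leaves in
colour, and appear sparsely (most frames contain few or no targets).

The package has five cooperating parts: target-number enhancement by
constrained copy-paste, high-resolution preprocessing, an improved cascade
detector, AP/mAP evaluation, and a synthetic-scene generator that stands in
for field data.

## Geometry conventions

Boxes are axis-aligned, 0-based, half-open on both axes (`x0 ≤ x < x1`), and
integer-valued in annotations, so areas and intersections are exact pixel
counts. The on-disk annotation dialect is COCO JSON with `[x, y, w, h]`
boxes; the conversion is lossless for integer coordinates. Model-internal
boxes (anchors, proposals, regressed boxes) are fractional.

## Target-number enhancement

Sparse per-image target counts starve a two-stage detector of positive ROIs.
The enhancement copies existing target crops to new locations subject to two
pixel-exact overlap rates both being **zero**:

- `u_outer = |copy box ∩ outer region| / |outer region|`, where the outer
  region is the background removed by foreground segmentation (leaves and
  trunk are "inner"). Zero keeps pasted insects on plausible substrate.
- `u_samples = |copy box ∩ ∪ sample boxes| / Σ area(sample boxes)`. Zero
  keeps pastes off existing targets. The sample set grows cumulatively —
  earlier pastes constrain later ones — otherwise pasted copies could stack.

Both rates are enforced at pixel granularity with exact zero, no tolerance.
Placement is seeded rejection sampling, uniform over top-left positions,
with `max_attempts = 100` per paste (the search procedure is our choice; the
constraint itself is the specification). A summed-area table over the free
pixel set distinguishes *guaranteed* failure (no feasible placement exists —
raised as `InfeasiblePlacementError`) from unlucky sampling (returns
`None`). Pasted boxes must additionally lie fully inside the image: partial
off-frame pastes are undefined and never useful.

Segmentation is a pluggable interface, not a trained network: the reference
pipeline used a pretrained semantic segmenter whose weights are not
available, so the default here is a documented colour/intensity threshold
(inner ⇔ green channel ≥ red and blue, and luminance ≥ 50), and a
user-supplied mask always wins. Synthetic scenes carry exact ground-truth
masks, so tests never depend on the threshold heuristic.

Colour harmonisation of pasted patches was a *manual* retouching step in the
original procedure. An automatic substitute (match the patch's intensity
mean/σ to a ring around the destination) is provided but **off by default**
and documented as non-equivalent.

How many pastes to make per image is not specified anywhere; the default
policy pastes until an image reaches `min_targets = 10` annotations (or
attempts are exhausted), with `copies_per_image` as an explicit override.

Offline resampling duplicates every enhanced record (factor 2 by default)
under fresh record identities. Duplicates share pixels; the downstream
*stochastic* preprocessing (scale draw, rotation draw) is what differentiates
them into distinct training samples, which is why the duplication does not
cause overfitting.

## Preprocessing

Camera frames run up to 4000 × 5000 px; naive downscaling to detector input
size erases the targets. Three steps, each with an explicit seeded RNG:

- **Nine-block tiling.** A 3 × 3 uniform grid (floor-divided boundaries, the
  last row/column absorbs remainders) partitions the frame exactly; tiles
  reassemble bit-exactly. Boxes are translated into tile coordinates and
  clipped; a clipped box is kept iff its clipped area ≥ `keep_fraction`
  (default 0.5) of the original, dropping near-empty slivers that would make
  misleading positives. `keep_fraction = 0` keeps every positive-area
  fragment, and then clipped areas sum exactly to the parent areas.
- **Multiscale resize.** One of two scales, `(1500, 1000)` and `(1333, 800)`,
  is drawn uniformly per sample. Each pair is read in the standard
  (long-side cap, short-side target) convention: scale the short side to the
  target unless that pushes the long side past the cap, in which case the
  long side is set to the cap. Aspect ratio is always preserved; output
  sizes round half-up (2000 × 1000 at (1333, 800) → 1333 × 667).
- **Random rotation.** With probability 0.5, rotate by 90°/180°/270°
  (uniform). Angles are restricted to right angles so axis-aligned boxes
  remap *exactly*; arbitrary angles would corrupt box geometry without
  instance masks. The remap is verified by painting boxes, rotating the
  raster, and re-extracting.

## Detector

A two-stage cascade detector whose feature extractor keeps a high-resolution
stream alive end to end.

**Backbone.** A parallel-resolution ("high-resolution network" style)
extractor: a two-conv stride-2 stem reaches 1/4 resolution, three
transitions add branches at 1/8, 1/16 and 1/32, and after each multi-branch
stage a fusion unit exchanges information all-to-all (strided 3 × 3 convs
downward, pointwise + nearest-upsample upward, elementwise sum, ReLU).
Contract: input H × W (divisible by 32) → four maps at H/4 … H/32.

**Attention.** Convolutional block attention (channel gate: global avg+max
pool → shared bottleneck MLP → sigmoid; spatial gate: channel mean+max →
7 × 7 conv → sigmoid) sits at five fixed sites: after each of the two stem
extraction convolutions, and on the fused high-resolution map of the
stage-2/3/4 fusion units. The original figure is ambiguous about whether
attention wraps or replaces fusion units; this wiring — attention *after*
fusion, on the stream the architecture exists to preserve — is the
interpretation the structural audit pins (five blocks exactly). Gate values
lie strictly in (0, 1); forcing gates to one makes each block the identity,
which is how the wiring audit is performed. Hyperparameters follow the
original attention module (reduction 16, spatial kernel 7; the tiny profile
uses reduction 4 because its branches are only 8–64 channels wide).

**Sawtooth dilated pyramid.** Per branch, parallel 3 × 3 convolutions at
dilation rates (1, 2, 5) plus a pointwise path, concatenated and projected
back to the branch width (padding = dilation preserves spatial dims). Large
uniform rates such as (1, 3, 6, 12) suit large objects; the sawtooth design
requires strictly increasing rates with consecutive pairs coprime, so the
union of sampling positions has no gridding holes — the validator rejects
(2, 4, 8) for exactly that reason. The internal composition (3 × 3 paths +
1 × 1 path + concat + projection) is an interpretation of a schematic
figure and is documented as such.

**Feature pyramid fusion.** Pointwise laterals project all four branches to
a uniform width; a top-down pass 2× nearest-upsamples and adds. No smoothing
convs follow the sums, so an impulse at the coarsest level propagates
unblurred to every finer level (traced in tests).

**Proposals.** One square anchor per pyramid cell (sizes 8/16/32/64 px at
strides 4/8/16/32 — deliberately small because targets are tens of pixels;
anchor specifics were never published, so these are the package's choice).
A shared 3 × 3 conv + two pointwise heads score objectness and regress
boxes; proposals are top-k by score, NMS at 0.7. During training the
ground-truth boxes are appended to the proposal set (standard cascade
practice) so every stage sees positives.

**Cascade heads.** Three stages with IoU thresholds (0.5, 0.6, 0.7) — the
canonical cascade settings; the source never states its thresholds — and
class-agnostic box regression. Stage t labels each ROI against the ground
truth at its threshold, computes per-ROI cross-entropy (+ smooth-L1 for
positives), and feeds stage t+1 its regressed boxes. Stage losses combine
with weights 1 : 0.5 : 0.25 into the total training loss. ROI features are
2 × 2 adaptive average pools on the pyramid level matched to the ROI's size.

**Hard-example mining.** Per batch per stage, ROIs are ranked by loss —
positives by classification + regression loss, negatives by classification
alone ("ROI loss" is otherwise unspecified) — and the top 64 positives and
top 192 negatives are kept; fewer candidates than a cap means all are kept.
Ties break by stable index. Selection is definitionally descending sort +
prefix and is tested against an independent full-sort oracle.

**Inference** averages the three stages' class posteriors, thresholds at
0.05, applies per-class NMS at 0.5, and returns scored boxes clipped to the
image.

The whole model runs on a small in-package reverse-mode autodiff engine
over NumPy arrays (float64; conv via strided window views + einsum). Every
primitive's gradient is verified against central finite differences in the
test suite. The `tiny` profile (branch widths 8/16/32/64, 64 × 64 training
scenes) exists so the full train/detect path runs on one CPU in minutes;
the default profile is structurally identical, just wider.

## Evaluation

AP for one class is the area under the precision–recall curve,
`AP = ∫₀¹ p(r) dr`. Because the definition is an integral, the default is
all-point (continuous) interpolation of the precision envelope; 11-point
sampling is available as an option. Matching is greedy in descending score
order at IoU ≥ 0.5 (the evaluation threshold was never stated; 0.5 is the
field default), each ground truth consumed at most once, score ties broken
by stable input order. mAP is the arithmetic mean of per-class APs; classes
with zero ground truths have *undefined* AP and are excluded from the mean
with a warning, never silently counted as 0.

## Synthetic scenes

The generator emulates the statistical structure of the field data rather
than its appearance: a textured earth-tone background; an irregular
leaf/trunk-like foreground region (thresholded smooth noise) covering a
configurable fraction (default 0.6) and matching the stored mask exactly;
dark elliptical targets, psyllid-like at 4–12 px and fly-like at 8–24 px
(preserving the ≈2× body-size ratio at test-friendly resolution, with a
4000 × 5000 profile for tiling); right-skewed per-image counts (truncated
geometric, p = 0.45 — most scenes hold ≤ 3 targets); and unannotated
distractor blobs sharing the targets' palette, mirroring the
branches/stems/dead-leaves confusers that motivate hard-example mining.

Two constructions make invariants exact rather than statistical: ellipse
stamps are forced to touch all four box edges, so every annotation is a
tight bounding box of its painted pixels; and targets are flat-coloured with
red strictly above green while canopy pixels always have green above red, so
painted target extents are recoverable from the raster exactly. Texture for
large frames is synthesised at a capped working resolution and bilinearly
upsampled, keeping generation cost bounded.

What the generator does **not** emulate: real illumination variation, motion
blur, occlusion, insect morphology, or manual colour harmonisation of
pastes. Passing tests on these scenes therefore validates geometry,
constraint enforcement, evaluation arithmetic and training mechanics — not
field accuracy. The published field accuracies (e.g. 88.78% psyllid AP,
90.21% mAP) require the original 500-image field dataset and GPU-scale
training, both out of scope here; what this package reproduces exactly is
the arithmetic those numbers obey (mAP = mean of per-class APs; the printed
AP differences) and every desk-scale property of the method.

## Numerical choices and problem sizes

- All randomness flows through explicit `numpy.random.Generator` objects;
  scene i of a dataset uses seed `base + i` so scenes regenerate in
  isolation.
- Zero-overlap constraints, tiling partitions and rotations are exact
  (integer/pixel arithmetic); no tolerances anywhere in the data path.
- Smoke training: 16 scenes of 64 × 64 px, 1–3 targets each, 200
  single-image SGD steps (lr 0.02, momentum 0.9, gradient clipping at norm
  5). Start/end comparisons use first- vs last-window means (window = max(5,
  n/10)) because single-step losses fluctuate with the image drawn.
- The autodiff engine is float64 throughout: at these problem sizes the
  exactness is worth more than the speed.

## Known limitations

- The default threshold segmenter is a heuristic, adequate for synthetic
  canopies and as a fallback; real deployments should supply masks from a
  proper semantic segmenter.
- The detector is trained from scratch at tiny scale in tests; no
  pretrained weights are shipped, and smoke training demonstrates loss
  descent, not detection quality.
- Harmonisation cannot reproduce manual retouching; enabling it changes
  pasted pixels and is off by default.
- AP under score ties depends on the documented stable tie order; a
  threshold-sweep oracle cannot distinguish tied rankings, so oracle
  comparisons use distinct scores.
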