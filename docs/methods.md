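# Methods

## The problem setting

Anchor-based detectors use a box-similarity metric in three places: label
assignment (which anchors train as positives for which ground truth),
non-maximum suppression, and the regression loss. For small objects
(side < ~32 px) IoU is a poor driver of all three: its value drops
steeply per pixel of localization error for small boxes, it is exactly 0
for every separated pair, and it cannot distinguish nested pairs that
differ only in center offset. This package implements a center-distance
metric designed for that regime and the branch-structured loss built on
it, together with baselines and the simulation machinery to examine their
behaviour without any image data.

## The TSD metric

`tsd(a, b, scale) = 1 - D_chess(a, b)^2 / S`, where `D_chess` is the
Chebyshev (L-infinity) distance between box centers and `S` the dataset
scale. Properties the tests verify: exactly 1 iff centers coincide; range
unbounded below; symmetric; translation invariant; independent of either
box's width and height at fixed centers (hence the deviation-curve
coincidence across box sizes); strictly decreasing with center distance
for separated pairs where IoU is flat at 0; sensitive to off-center
containment where IoU is flat at the area ratio.

**The scale S.** S is the arithmetic mean area (px^2) of the ground-truth
boxes, so `D_chess^2 / S` is dimensionless; `sqrt(S)` plays the role of an
average side length. Only the area interpretation is dimensionally
coherent with the squared distance in the numerator. S is computed once
per ground-truth collection (`dataset_scale`) and passed explicitly to
every TSD evaluation — it is a dataset constant, never recomputed per
pair. When a caller has ground truths from a specific split, S is
whatever collection they pass; the package takes no position on
train-versus-all-splits because the choice is the caller's data contract.

## The TSD loss

Branch selection uses the separated / intersect / contain trichotomy of
`classify_relationship`. Boundary conventions (the loss definition leaves
them open; these are this package's choices, fixed here and asserted in
tests):

- **Edge- or corner-touching pairs are SEPARATED.** Their overlap has
  measure zero, IoU degenerates to 0 there, and the separated branch
  remains well defined.
- **Identical boxes (mutual containment) are CONTAIN.** The contain
  branch with `r1 = r2` is the only branch that returns exactly 0, which
  is the right answer for a perfect prediction.
- Containment counts boundary contact as inside.

Branch forms and variables:

| branch    | x                         | loss        | dloss/dx |
|-----------|---------------------------|-------------|----------|
| separated | `D_chess^2 / S`           | `x`         | `1`      |
| intersect | `theta` (radians)         | `1 - cos x` | `sin x`  |
| contain   | `abs(r1 - r2)` (pixels)   | `1 - e^-x`  | `e^-x`   |

`theta` comes from the law of cosines on the triangle with sides `r1`,
`r2` (circumcircle radii = half-diagonals) and the **Euclidean** center
distance `d`. The separated branch uses the Chebyshev distance but the
intersect branch must use the Euclidean one: the law of cosines is a
Euclidean statement and is geometrically meaningless under the Chebyshev
norm.

**Clamping.** `cos_theta` clamps the raw value to [-1, 1]. Pairs that
intersect deeply without either box containing the other (e.g. a thin
tall box crossed by a wide short one, `d < |r1 - r2|`) push the raw
law-of-cosines value above 1; clamping keeps theta real and the loss
non-negative. `cos_theta` on a non-intersecting pair raises — branch
misuse is an error, not a silent extrapolation.

**Dimensionality of the contain branch.** The exponent `|r1 - r2|` is in
raw pixels, so the contain loss is not scale-free. The printed form is
kept as the default; `tsd_loss(..., normalize_contain_radius=True)`
divides the exponent by `sqrt(S)` for users who want all three branches
dimensionless. Known limitation, not silently "fixed".

**Discontinuity at branch transitions.** The three branch forms do not
join continuously at relationship boundaries — the truncation is the
design, trading continuity for bounded gradients and
structure-appropriate penalties. Tests assert branch values and the
within-branch gradient identities, never cross-branch continuity. A
related asymmetry is accepted as defined: the separated branch is
unbounded above while intersect and contain are bounded by 2 and 1.

**Gradient bounds.** `1`, `|sin x| <= 1`, `e^-x in (0, 1]` over the
branch domains (`x >= 0`; `theta in [0, pi]`) give a uniform gradient
magnitude bound of 1 — verified against central finite differences at
relative tolerance 1e-6.

**Aggregation.** `batch_regression_loss` is the unweighted mean over
pairs — the common detector reduction, keeping values comparable across
batch sizes. The TSD loss is computed directly on box pairs, not on
encoded regression deltas; smooth L1 (the baseline) is computed on the
standard `(dx/w, dy/h, log w-ratio, log h-ratio)` encoding.

**Focal loss.** Standard form with defaults `alpha = 0.5, gamma = 2`.
`focal_loss_total` normalizes the per-image sum by the number of anchors
assigned to a ground truth rather than all anchors, because nearly all
anchors are easy negatives with negligible loss and total-anchor
normalization would drown the signal.

## Assignment and NMS

`generate_anchors` uses the area-preserving ratio convention
(`w = size*sqrt(ratio)`, `h = size/sqrt(ratio)`), one anchor per
(size, ratio) at each stride-cell center, sizes (8, 16, 32, 64, 128) and
ratios (0.5, 1, 2) by default — a pyramid extended one octave downward
for the small-object regime. Anchors are not clipped to the image
(`AnchorGrid.clipped` is the opt-in), and the enumeration is independent
of the metric, which a test asserts.

`assign_labels` is max-quality thresholding (positive >= 0.7, negative
< 0.3 by default) with optional force-matching: each ground truth claims
its best anchor, ties broken toward the lowest anchor index for
determinism. When two ground truths share a best anchor, the later one
falls back to its next-best unclaimed anchor, so the contract "every
ground truth has at least one positive" holds whenever there are at
least as many anchors as ground truths. The IoU thresholds are the
classic two-stage-detector convention; for TSD the same numbers are
applied **on the TSD scale** — a convention of this package (TSD shares
the "1 = perfect" calibration), not an externally validated choice, and
all thresholds are exposed in the API and CLI config. TSD values below
zero are compared as-is, with no flooring.

`nms` is the standard pairwise greedy form: keep the best-scoring box,
drop everything with similarity >= threshold to it, repeat. Score ties
break toward the lower input index. The implementation is verified
index-by-index against an independently written O(n^2) oracle. Both IoU-
and TSD-NMS are exposed; TSD-NMS suppresses by center distance only, so
it ignores size differences between candidate boxes — callers can mix
metrics across the assignment/NMS/loss roles.

## The simulation suite

`deviation_curve` re-creates the size-sensitivity analysis: box B (half
the side of A by default) starts concentric with A and is drawn along A's
diagonal. "Deviation k" means the center offset vector is `(k, k)` — so
the Chebyshev distance equals k exactly and the TSD curve is exactly
`1 - k^2/S` at integral-pixel abscissae — rather than Euclidean length k
along the diagonal. The four-sizes default `(8, 16, 32, 64)` spans the
small-object range; the interpretation of "four scenarios" as four sizes
of A is this package's, as is the S supplied per call (the analysis is
S-generic).

`make_scene` emulates the traits that matter for assignment experiments:
dense, small (default sides 4-16 px, inside the sub-32 px regime),
uniformly placed ground truths; detections derived from them by Gaussian
center jitter (default sd 2 px), 5% size jitter, duplicates at rate 0.2,
and scores `exp(-|jitter|/side)` — a deterministic monotone surrogate for
detector confidence. It does **not** emulate photometrics, occlusion,
aspect-ratio extremes, missed detections, or class confusion; passing
tests show metric/assignment behaviour under controlled geometry, not
end-to-end detector accuracy on real imagery. All generators are
seed-deterministic and bit-reproducible.

`assignment_experiment` reports positives-per-ground-truth, the fraction
of ground truths with no positive anchor (without force-matching), and
mean best-match quality, stratified by object side — quantifying the
sample starvation of small objects under IoU thresholds.

## Numerical and interface choices

- Boxes are continuous corner coordinates; zero-area and non-finite boxes
  are rejected at construction (circumradius and IoU denominators
  degenerate).
- Metrics have scalar forms on `Box` pairs and broadcasting array forms;
  `pairwise_matrix` vectorizes anchor-by-ground-truth qualities.
- CSV box files round-trip losslessly (shortest-repr floats); derived CLI
  tables use 6 significant digits for readable diffs. COCO-dialect JSON
  keeps full precision, with the top-left + width/height `bbox`
  convention converted to corners at the boundary.
- Problem sizes in the test suite (10,000-pair sweeps, 100 seeded scenes
  of 50 boxes, 1000-point gradient grids, a 1000x1000 sub-pixel
  rasterization oracle) are chosen so the whole suite runs in well under
  a minute while still exercising every branch and boundary case.

## Known limitations

- No training: the detector context (backbone, RPN heads, RoI pooling)
  is out of scope; the package evaluates metrics and losses on boxes.
- TSD ignores box size entirely at fixed centers — by design for
  assignment robustness, but it means the metric alone cannot rank two
  detections that differ only in size; the loss's contain/intersect
  branches reintroduce size sensitivity.
- TSD thresholds for assignment and NMS are conventions, not tuned
  values; users should treat them as starting points.
- Rotated/polygonal/3D boxes and Wasserstein-style distributional
  metrics are out of scope.
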