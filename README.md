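# tsdbox

Bounding-box similarity and regression loss for **small, densely packed
objects** — the regime of automated pest-trap imaging and similar
biological monitoring, where most objects are under 32 px a side and IoU
starts to fail: a 1-pixel localization error costs a 4x4 box far more IoU
than a 32x32 box, separated box pairs all score 0, and nested pairs all
score the same area ratio.

The package implements the **truncated structurally aware distance (TSD)**
metric and its loss, plus the standard IoU/GIoU/DIoU/CIoU baselines, a
metric-pluggable label assigner and NMS, and a simulation suite for the
metric-level behavioural analyses — no image data or GPU required.

## The metric and the loss

With box centers $(x_1,y_1)$, $(x_2,y_2)$ and the Chebyshev center
distance $D_{chess} = \max(|x_1-x_2|, |y_1-y_2|)$,

$$\mathrm{TSD} = 1 - \frac{D_{chess}^2}{S},$$

where $S$ is the **dataset scale**: the mean area of all ground-truth
boxes, computed once per dataset. TSD is 1 exactly when centers coincide,
falls off with center offset *independently of box size*, and has range
$(-\infty, 1]$, so it keeps ranking even fully separated pairs.

The TSD **loss** selects one of three penalties by the structural
relationship of the pair (separated / intersect / contain):

$$\mathcal{L} = \begin{cases} D_{chess}^2 / S & \text{separated} \\ 1-\cos\theta & \text{intersect} \\ 1-e^{-|r_1-r_2|} & \text{contain} \end{cases}$$

with $r_1, r_2$ the circumcircle radii (half-diagonals) of the two boxes
and $\cos\theta = (r_1^2+r_2^2-d^2)/(2 r_1 r_2)$ from the law of cosines
on the Euclidean center distance $d$. Written as functions of a single
variable $x$, the branch gradients are $1$, $\sin x$ and $e^{-x}$ — all
bounded by 1, so the loss never explodes.

## Worked example

```python
from tsdbox import (Box, DatasetScale, iou, tsd, tsd_loss, deviation_curve)

s = DatasetScale(100.0)                 # mean ground-truth area: 100 px^2
gt  = Box.from_center(50, 50, 6, 6)     # a 6x6 ground truth
det = Box.from_center(53, 52, 6, 6)     # detection, 3 px off in x, 2 in y

iou(gt, det)          # 0.2    -- 80% of the IoU gone after a 3-px miss
tsd(gt, det, s)       # 0.91   -- TSD: Chebyshev distance 3, 1 - 9/100

tsd_loss(gt, det, s)
# LossBreakdown(value=0.3611, branch=INTERSECT,
#               branch_variable_x=0.8777, gradient_dx=0.7693)
# the pair overlaps, so the loss is 1 - cos(theta) with theta = 0.8777 rad

far = Box.from_center(80, 50, 6, 6)     # 30 px away: no overlap at all
iou(gt, far)          # 0.0    -- IoU can no longer rank this detection
tsd(gt, far, s)       # -8.0   -- TSD still orders it: 1 - 900/100
tsd_loss(gt, far, s)  # value=9.0, branch=SEPARATED, gradient 1

# the size-insensitivity claim, verified directly: one deviation curve
# per box side, and they are elementwise identical
for side in (8, 16, 32, 64):
    print(deviation_curve(side, 0.5, s, "tsd", max_dev=5).metric_value)
# [1.   0.99 0.96 0.91 0.84 0.75]   (all four rows identical)
```

The same operations are scriptable from the shell — `tsdbox metric`,
`scale`, `loss`, `assign`, `nms`, `curve`, `scene`, `experiment`; every
subcommand writes a deterministic CSV. For example:

```sh
tsdbox curve --metric tsd --sides 8,16,32,64 --scale-s 100 --out curve.csv
tsdbox scene --n-objects 100 --seed 7 --out scene.json   # synthetic fixture
```

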