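"""Box-similarity metrics: TSD and the IoU family.

The truncated structurally aware distance (TSD) measures box similarity as

    TSD = 1 - D_chess(a, b)**2 / S

where ``D_chess`` is the Chebyshev (L-infinity) distance between the two box
centers and ``S`` is the dataset scale — the mean area of all ground-truth
boxes, so that the squared pixel distance becomes dimensionless. TSD is 1
exactly when the centers coincide, decreases with center offset regardless
of box sizes, and is unbounded below: its range is (-inf, 1]. Unlike IoU it
keeps discriminating between separated boxes (where IoU is flat at 0) and
between off-center containments (where IoU is flat at the area ratio), and
its drop under a fixed pixel deviation does not depend on box size — the
property that makes it suitable for objects smaller than ~32 px.

IoU, GIoU, DIoU and CIoU are provided as baselines behind the same registry
so label assignment and NMS can be run with any of the five metrics.

All metrics come in a scalar form (two :class:`~tsdbox.boxes.Box` objects)
and a broadcasting array form on ``(..., 4)`` corner arrays; the scalar
forms delegate to the array forms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np

from .boxes import Box, boxes_to_array

__all__ = [
    "DatasetScale",
    "dataset_scale",
    "tsd",
    "iou",
    "giou",
    "diou",
    "ciou",
    "METRICS",
    "metric_names",
    "get_metric",
    "pairwise_matrix",
]


@dataclass(frozen=True)
class DatasetScale:
    """The standardization constant S of the TSD metric.

    Attributes
    ----------
    S
        Mean ground-truth box area in pixels squared; ``sqrt(S)`` plays the
        role of an average side length. Must be positive.
    n_boxes
        Number of ground-truth boxes the mean was taken over.
    """

    S: float
    n_boxes: int = 1

    def __post_init__(self) -> None:
        if not (self.S > 0 and np.isfinite(self.S)):
            raise ValueError(f"dataset scale S must be positive and finite, got {self.S}")
        if self.n_boxes < 1:
            raise ValueError(f"n_boxes must be >= 1, got {self.n_boxes}")


def dataset_scale(ground_truths: Sequence[Box] | Iterable[Box]) -> DatasetScale:
    """Compute S as the arithmetic mean of w*h over all ground-truth boxes.

    S is computed once per dataset and passed explicitly to every TSD
    evaluation; it is never recomputed per pair.

    Raises
    ------
    ValueError
        If the collection is empty (S is undefined).
    """
    gts = list(ground_truths)
    if not gts:
        raise ValueError("dataset scale S is undefined for an empty ground-truth set")
    areas = [b.area for b in gts]
    return DatasetScale(S=float(np.mean(areas)), n_boxes=len(gts))


# ---------------------------------------------------------------------------
# array forms: a, b are (..., 4) corner arrays, broadcast against each other
# ---------------------------------------------------------------------------


def _split(arr: np.ndarray):
    a = np.asarray(arr, dtype=float)
    return a[..., 0], a[..., 1], a[..., 2], a[..., 3]


def _centers_wh(arr: np.ndarray):
    x0, y0, x1, y1 = _split(arr)
    return 0.5 * (x0 + x1), 0.5 * (y0 + y1), x1 - x0, y1 - y0


def _intersection(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ax0, ay0, ax1, ay1 = _split(a)
    bx0, by0, bx1, by1 = _split(b)
    iw = np.minimum(ax1, bx1) - np.maximum(ax0, bx0)
    ih = np.minimum(ay1, by1) - np.maximum(ay0, by0)
    return np.clip(iw, 0.0, None) * np.clip(ih, 0.0, None)


def iou_array(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    inter = _intersection(a, b)
    _, _, wa, ha = _centers_wh(a)
    _, _, wb, hb = _centers_wh(b)
    union = wa * ha + wb * hb - inter
    return inter / union


def tsd_array(a: np.ndarray, b: np.ndarray, S: float) -> np.ndarray:
    cxa, cya, _, _ = _centers_wh(a)
    cxb, cyb, _, _ = _centers_wh(b)
    d = np.maximum(np.abs(cxa - cxb), np.abs(cya - cyb))
    return 1.0 - d * d / S


def giou_array(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ax0, ay0, ax1, ay1 = _split(a)
    bx0, by0, bx1, by1 = _split(b)
    cw = np.maximum(ax1, bx1) - np.minimum(ax0, bx0)
    ch = np.maximum(ay1, by1) - np.minimum(ay0, by0)
    inter = _intersection(a, b)
    union = (ax1 - ax0) * (ay1 - ay0) + (bx1 - bx0) * (by1 - by0) - inter
    enclosing = cw * ch
    return inter / union - (enclosing - union) / enclosing


def diou_array(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ax0, ay0, ax1, ay1 = _split(a)
    bx0, by0, bx1, by1 = _split(b)
    cw = np.maximum(ax1, bx1) - np.minimum(ax0, bx0)
    ch = np.maximum(ay1, by1) - np.minimum(ay0, by0)
    cxa, cya, _, _ = _centers_wh(a)
    cxb, cyb, _, _ = _centers_wh(b)
    d2 = (cxa - cxb) ** 2 + (cya - cyb) ** 2
    c2 = cw * cw + ch * ch
    return iou_array(a, b) - d2 / c2


def ciou_array(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    # plain alpha*v aspect-ratio penalty, no gradient rescaling trick
    _, _, wa, ha = _centers_wh(a)
    _, _, wb, hb = _centers_wh(b)
    v = (4.0 / np.pi**2) * (np.arctan(wa / ha) - np.arctan(wb / hb)) ** 2
    i = iou_array(a, b)
    with np.errstate(invalid="ignore", divide="ignore"):
        alpha = np.where(v > 0, v / ((1.0 - i) + v), 0.0)
    return diou_array(a, b) - alpha * v


# ---------------------------------------------------------------------------
# scalar forms
# ---------------------------------------------------------------------------


def _pair(a: Box, b: Box):
    return np.asarray(a.as_tuple(), dtype=float), np.asarray(b.as_tuple(), dtype=float)


def tsd(a: Box, b: Box, scale: DatasetScale) -> float:
    """TSD similarity, ``1 - D_chess(a,b)**2 / S``.

    Symmetric, translation invariant, independent of both boxes' widths and
    heights at fixed centers; equals 1 iff the centers coincide and has no
    lower bound.
    """
    if not isinstance(scale, DatasetScale):
        scale = DatasetScale(S=float(scale))
    aa, bb = _pair(a, b)
    return float(tsd_array(aa, bb, scale.S))


def iou(a: Box, b: Box) -> float:
    """Intersection over union, in [0, 1]; 0 for disjoint pairs, 1 iff identical."""
    aa, bb = _pair(a, b)
    return float(iou_array(aa, bb))


def giou(a: Box, b: Box) -> float:
    """Generalized IoU: IoU minus the enclosing-box waste ratio; range (-1, 1]."""
    aa, bb = _pair(a, b)
    return float(giou_array(aa, bb))


def diou(a: Box, b: Box) -> float:
    """Distance IoU: IoU minus d^2/c^2 with d the Euclidean center distance
    and c the enclosing-box diagonal."""
    aa, bb = _pair(a, b)
    return float(diou_array(aa, bb))


def ciou(a: Box, b: Box) -> float:
    """Complete IoU: DIoU minus the aspect-ratio penalty alpha*v with
    v = (4/pi^2)(arctan(w_a/h_a) - arctan(w_b/h_b))^2 and
    alpha = v / ((1 - IoU) + v)."""
    aa, bb = _pair(a, b)
    return float(ciou_array(aa, bb))


# ---------------------------------------------------------------------------
# registry: similarity metrics keyed by name, all with the uniform signature
# f(a, b, scale) so assignment and NMS are metric-pluggable
# ---------------------------------------------------------------------------

MetricFn = Callable[[np.ndarray, np.ndarray, float | None], np.ndarray]

METRICS: dict[str, MetricFn] = {
    "iou": lambda a, b, S=None: iou_array(a, b),
    "giou": lambda a, b, S=None: giou_array(a, b),
    "diou": lambda a, b, S=None: diou_array(a, b),
    "ciou": lambda a, b, S=None: ciou_array(a, b),
    "tsd": lambda a, b, S=None: tsd_array(a, b, _require_scale(S)),
}


def _require_scale(S) -> float:
    if S is None:
        raise ValueError("metric 'tsd' requires the dataset scale S")
    S = float(S.S) if isinstance(S, DatasetScale) else float(S)
    if S <= 0:
        raise ValueError(f"dataset scale S must be positive, got {S}")
    return S


def metric_names() -> list[str]:
    return sorted(METRICS)


def get_metric(name: str) -> MetricFn:
    """Look up a metric by registry name ('iou', 'giou', 'diou', 'ciou', 'tsd')."""
    try:
        return METRICS[name]
    except KeyError:
        raise ValueError(
            f"unknown metric {name!r}; registered metrics: {metric_names()}"
        ) from None


def pairwise_matrix(
    boxes_a: Sequence[Box] | np.ndarray,
    boxes_b: Sequence[Box] | np.ndarray,
    metric_name: str,
    scale: DatasetScale | float | None = None,
) -> np.ndarray:
    """All-pairs similarity matrix of shape ``(len(a), len(b))``."""
    fn = get_metric(metric_name)
    a = boxes_a if isinstance(boxes_a, np.ndarray) else boxes_to_array(boxes_a)
    b = boxes_b if isinstance(boxes_b, np.ndarray) else boxes_to_array(boxes_b)
    if a.size == 0 or b.size == 0:
        return np.zeros((a.shape[0] if a.ndim == 2 else 0, b.shape[0] if b.ndim == 2 else 0))
    return fn(a[:, None, :], b[None, :, :], scale)
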