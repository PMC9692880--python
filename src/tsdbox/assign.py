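"""Anchor generation, metric-pluggable label assignment, and NMS.

These are the three roles a similarity metric plays inside a region
proposal network: tiling reference boxes (anchors) over the image, deciding
which anchors count as positive/negative training examples for each ground
truth, and suppressing near-duplicate detections. All three accept any
registered metric ('iou', 'giou', 'diou', 'ciou', 'tsd'), so the effect of
swapping IoU for TSD can be studied in isolation — the anchor enumeration
never depends on the metric.

Thresholds follow the classic Faster R-CNN convention (positive >= 0.7,
negative < 0.3, NMS at 0.5). For TSD the same defaults are used on the TSD
scale, since TSD shares IoU's "1 = perfect" calibration; these TSD
thresholds are a convention of this package, not externally validated, and
are exposed in every signature and in the CLI config. TSD values can be
negative and thresholds are compared on the raw metric scale with no
flooring, which preserves TSD's ability to rank separated boxes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .boxes import Box, array_to_boxes, boxes_to_array
from .metrics import DatasetScale, get_metric, pairwise_matrix

__all__ = [
    "POSITIVE",
    "NEGATIVE",
    "IGNORE",
    "AnchorGrid",
    "MatchResult",
    "generate_anchors",
    "assign_labels",
    "nms",
    "DEFAULT_ANCHOR_SIZES",
    "DEFAULT_ASPECT_RATIOS",
]

# per-anchor label codes
POSITIVE = 1
NEGATIVE = 0
IGNORE = -1

# region-proposal defaults for the dense small-object regime: one extra
# small size (8 px) below the usual pyramid, three area-preserving ratios
DEFAULT_ANCHOR_SIZES: tuple[float, ...] = (8.0, 16.0, 32.0, 64.0, 128.0)
DEFAULT_ASPECT_RATIOS: tuple[float, ...] = (0.5, 1.0, 2.0)


@dataclass(frozen=True)
class AnchorGrid:
    """Anchors tiled over an image grid.

    ``anchors`` is an ``(N, 4)`` corner array ordered cell-major (row, then
    column, then size, then ratio); ``N = grid_h * grid_w * len(sizes) *
    len(aspect_ratios)``. Anchors may extend past the image bounds —
    clipping is an explicit opt-in, as in standard RPN practice.
    """

    anchors: np.ndarray
    stride: float
    sizes: tuple[float, ...]
    aspect_ratios: tuple[float, ...]
    grid_shape: tuple[int, int] = (0, 0)

    def __len__(self) -> int:
        return self.anchors.shape[0]

    @property
    def boxes(self) -> list[Box]:
        return array_to_boxes(self.anchors)

    def clipped(self, image_w: float, image_h: float) -> "AnchorGrid":
        """Return a copy with anchors clipped to the image rectangle."""
        a = self.anchors.copy()
        a[:, [0, 2]] = np.clip(a[:, [0, 2]], 0.0, image_w)
        a[:, [1, 3]] = np.clip(a[:, [1, 3]], 0.0, image_h)
        keep = (a[:, 2] > a[:, 0]) & (a[:, 3] > a[:, 1])
        return AnchorGrid(a[keep], self.stride, self.sizes, self.aspect_ratios, self.grid_shape)


@dataclass(frozen=True)
class MatchResult:
    """Per-anchor assignment: label, matched ground truth, and match quality.

    ``labels[i]`` is POSITIVE (1), NEGATIVE (0) or IGNORE (-1);
    ``matched_gt_index[i]`` is the argmax ground truth for anchor ``i`` or
    -1 when there are no ground truths; ``match_quality[i]`` is the metric
    value against that ground truth (-inf with no ground truths).
    """

    labels: np.ndarray
    matched_gt_index: np.ndarray
    match_quality: np.ndarray

    @property
    def positive_indices(self) -> np.ndarray:
        return np.flatnonzero(self.labels == POSITIVE)

    def positives_per_gt(self, n_gts: int) -> np.ndarray:
        """Count of positive anchors matched to each ground truth."""
        counts = np.zeros(n_gts, dtype=int)
        pos = self.labels == POSITIVE
        for g in self.matched_gt_index[pos]:
            if g >= 0:
                counts[g] += 1
        return counts


def generate_anchors(
    image_w: float,
    image_h: float,
    stride: float,
    sizes: Sequence[float] = DEFAULT_ANCHOR_SIZES,
    ratios: Sequence[float] = DEFAULT_ASPECT_RATIOS,
) -> AnchorGrid:
    """Tile one anchor per (size, ratio) at every grid-cell center.

    Cells have side ``stride``; the cell at grid position (i, j) has its
    center at ``((j + 0.5) * stride, (i + 0.5) * stride)``. Each anchor has
    area ``size**2`` and aspect ratio w/h = ratio, i.e. ``w = size *
    sqrt(ratio)`` and ``h = size / sqrt(ratio)`` — the area-preserving ratio
    convention. The grid covers the image with ``ceil(image / stride)``
    cells per axis; anchors are not clipped to the image.
    """
    if image_w <= 0 or image_h <= 0 or stride <= 0:
        raise ValueError("image dimensions and stride must be positive")
    sizes = tuple(float(s) for s in sizes)
    ratios = tuple(float(r) for r in ratios)
    if not sizes or not ratios:
        raise ValueError("sizes and ratios must be non-empty")
    if any(s <= 0 for s in sizes) or any(r <= 0 for r in ratios):
        raise ValueError("sizes and ratios must be positive")

    grid_w = math.ceil(image_w / stride)
    grid_h = math.ceil(image_h / stride)
    cx = (np.arange(grid_w) + 0.5) * stride
    cy = (np.arange(grid_h) + 0.5) * stride

    # per-cell template of (size, ratio) half-extents
    ws = np.array([s * math.sqrt(r) for s in sizes for r in ratios])
    hs = np.array([s / math.sqrt(r) for s in sizes for r in ratios])

    cyy, cxx = np.meshgrid(cy, cx, indexing="ij")
    centers = np.stack([cxx.ravel(), cyy.ravel()], axis=1)  # (cells, 2)
    n_cells, n_tpl = centers.shape[0], ws.shape[0]
    anchors = np.empty((n_cells, n_tpl, 4))
    anchors[:, :, 0] = centers[:, None, 0] - 0.5 * ws[None, :]
    anchors[:, :, 1] = centers[:, None, 1] - 0.5 * hs[None, :]
    anchors[:, :, 2] = centers[:, None, 0] + 0.5 * ws[None, :]
    anchors[:, :, 3] = centers[:, None, 1] + 0.5 * hs[None, :]
    return AnchorGrid(
        anchors.reshape(-1, 4), float(stride), sizes, ratios, (grid_h, grid_w)
    )


def assign_labels(
    anchors: AnchorGrid | Sequence[Box] | np.ndarray,
    gts: Sequence[Box],
    metric_name: str = "iou",
    scale: DatasetScale | float | None = None,
    pos_threshold: float = 0.7,
    neg_threshold: float = 0.3,
    force_match: bool = True,
) -> MatchResult:
    """Assign positive/negative/ignore labels to anchors by metric quality.

    Each anchor's quality is its maximum metric value over all ground
    truths; anchors with quality >= ``pos_threshold`` are positive, quality
    < ``neg_threshold`` negative, in between ignored. With ``force_match``,
    the best anchor of every ground truth (ties broken toward the lowest
    anchor index) is additionally positive and matched to that ground
    truth, so no ground truth is left without a training example. With no
    ground truths all anchors are negative (quality -inf).
    """
    if pos_threshold < neg_threshold:
        raise ValueError(
            f"pos_threshold ({pos_threshold}) must be >= neg_threshold ({neg_threshold})"
        )
    get_metric(metric_name)  # fail fast on unknown names
    if isinstance(anchors, AnchorGrid):
        anchor_arr = anchors.anchors
    elif isinstance(anchors, np.ndarray):
        anchor_arr = anchors
    else:
        anchor_arr = boxes_to_array(anchors)
    n = anchor_arr.shape[0]

    if len(gts) == 0:
        return MatchResult(
            labels=np.full(n, NEGATIVE, dtype=np.int8),
            matched_gt_index=np.full(n, -1, dtype=int),
            match_quality=np.full(n, -np.inf),
        )

    q = pairwise_matrix(anchor_arr, gts, metric_name, scale)  # (n, n_gt)
    quality = q.max(axis=1)
    matched = q.argmax(axis=1)

    labels = np.full(n, IGNORE, dtype=np.int8)
    labels[quality < neg_threshold] = NEGATIVE
    labels[quality >= pos_threshold] = POSITIVE

    if force_match and n > 0:
        # each gt claims its best anchor (ties -> lowest anchor index); if
        # another gt already claimed it, fall back to the next-best anchor so
        # no gt is left without a positive (only possible when n >= n_gt)
        forced: set[int] = set()
        for g in range(q.shape[1]):
            order = np.argsort(-q[:, g], kind="stable")
            a_idx = next((int(i) for i in order if int(i) not in forced), int(order[0]))
            forced.add(a_idx)
            labels[a_idx] = POSITIVE
            matched[a_idx] = g
    return MatchResult(labels=labels, matched_gt_index=matched, match_quality=quality)


def nms(
    boxes: Sequence[Box] | np.ndarray,
    scores: Sequence[float] | np.ndarray,
    metric_name: str = "iou",
    scale: DatasetScale | float | None = None,
    threshold: float = 0.5,
) -> list[int]:
    """Greedy non-maximum suppression under any registered metric.

    Repeatedly keeps the highest-scoring remaining box and discards every
    remaining box whose similarity to it is >= ``threshold``. Score ties are
    broken toward the lower input index. Returns kept indices in
    descending-score order; any two kept boxes have pairwise similarity
    below the threshold.
    """
    arr = boxes if isinstance(boxes, np.ndarray) else boxes_to_array(boxes)
    scores = np.asarray(scores, dtype=float)
    if arr.shape[0] != scores.shape[0]:
        raise ValueError(
            f"boxes ({arr.shape[0]}) and scores ({scores.shape[0]}) length mismatch"
        )
    if arr.shape[0] == 0:
        return []
    fn = get_metric(metric_name)
    order = np.argsort(-scores, kind="stable")  # stable: ties -> lower index
    kept: list[int] = []
    alive = np.ones(arr.shape[0], dtype=bool)
    for idx in order:
        if not alive[idx]:
            continue
        kept.append(int(idx))
        sims = fn(arr[idx][None, :], arr[alive], scale)
        alive_idx = np.flatnonzero(alive)
        alive[alive_idx[sims >= threshold]] = False
    return kept
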