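"""Independent oracles used only by the tests.

These deliberately avoid the package's analytic code paths: overlap areas
are counted on a rasterized sub-pixel grid, and NMS is re-derived as a
plain O(n^2) scan. They are slow and simple on purpose.
"""

from __future__ import annotations

import numpy as np

from tsdbox.boxes import Box
from tsdbox.metrics import DatasetScale, get_metric


def rasterized_intersection_area(a: Box, b: Box, grid: int = 1000) -> float:
    """Overlap area by counting sub-pixel cell centers inside both boxes."""
    x_lo = min(a.x_min, b.x_min)
    x_hi = max(a.x_max, b.x_max)
    y_lo = min(a.y_min, b.y_min)
    y_hi = max(a.y_max, b.y_max)
    xs = np.linspace(x_lo, x_hi, grid, endpoint=False) + (x_hi - x_lo) / (2 * grid)
    ys = np.linspace(y_lo, y_hi, grid, endpoint=False) + (y_hi - y_lo) / (2 * grid)
    cell = ((x_hi - x_lo) / grid) * ((y_hi - y_lo) / grid)
    xx, yy = np.meshgrid(xs, ys)

    def inside(box: Box) -> np.ndarray:
        return (
            (xx >= box.x_min) & (xx <= box.x_max)
            & (yy >= box.y_min) & (yy <= box.y_max)
        )

    return float(np.count_nonzero(inside(a) & inside(b)) * cell)


def rasterized_iou(a: Box, b: Box, grid: int = 1000) -> float:
    """IoU by counting cells inside both versus inside either."""
    x_lo = min(a.x_min, b.x_min)
    x_hi = max(a.x_max, b.x_max)
    y_lo = min(a.y_min, b.y_min)
    y_hi = max(a.y_max, b.y_max)
    xs = np.linspace(x_lo, x_hi, grid, endpoint=False) + (x_hi - x_lo) / (2 * grid)
    ys = np.linspace(y_lo, y_hi, grid, endpoint=False) + (y_hi - y_lo) / (2 * grid)
    xx, yy = np.meshgrid(xs, ys)

    def inside(box: Box) -> np.ndarray:
        return (
            (xx >= box.x_min) & (xx <= box.x_max)
            & (yy >= box.y_min) & (yy <= box.y_max)
        )

    in_a, in_b = inside(a), inside(b)
    union = np.count_nonzero(in_a | in_b)
    if union == 0:
        return 0.0
    return float(np.count_nonzero(in_a & in_b) / union)


def brute_force_nms(
    boxes: list[Box],
    scores: list[float],
    metric_name: str = "iou",
    scale: DatasetScale | float | None = None,
    threshold: float = 0.5,
) -> list[int]:
    """Quadratic greedy NMS, re-derived independently of the package's loop."""
    fn = get_metric(metric_name)

    def sim(i: int, j: int) -> float:
        import numpy as np

        return float(
            fn(
                np.asarray(boxes[i].as_tuple())[None, :],
                np.asarray(boxes[j].as_tuple())[None, :],
                scale,
            )[0]
        )

    remaining = sorted(range(len(boxes)), key=lambda i: (-scores[i], i))
    kept: list[int] = []
    while remaining:
        best = remaining.pop(0)
        kept.append(best)
        remaining = [i for i in remaining if sim(best, i) < threshold]
    return kept
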