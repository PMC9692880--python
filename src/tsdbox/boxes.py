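"""Axis-aligned bounding boxes and their structural relationships.

A box is the atom of everything in this package: a rectangle in continuous
pixel coordinates, stored as its two corners ``(x_min, y_min, x_max, y_max)``.
Derived geometry (center, side lengths, circumcircle radius), center
distances, rectangle intersection, and the separated / intersect / contain
trichotomy that selects the TSD-loss branch all live here.

Coordinates are continuous — there is no half-open pixel-index convention,
because every downstream formula is geometric (centers, side lengths,
areas). Degenerate boxes (zero or negative width/height, non-finite
coordinates) are rejected at construction: circumradius and IoU
denominators are undefined for them.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Box",
    "Relationship",
    "center",
    "circumradius",
    "chebyshev_center_distance",
    "euclidean_center_distance",
    "intersection_area",
    "union_area",
    "enclosing_box",
    "classify_relationship",
    "boxes_to_array",
    "array_to_boxes",
]


class Relationship(enum.Enum):
    """Structural relationship of an ordered pair of boxes.

    Exactly one of the three values holds for any pair (trichotomy), and the
    classification is symmetric in its arguments.

    - ``SEPARATED``: zero overlap area, including boxes touching only along
      an edge or at a corner (their overlap degenerates to measure zero).
    - ``INTERSECT``: positive overlap area but neither box contains the other.
    - ``CONTAIN``: every corner of one box lies inside or on the boundary of
      the other; identical boxes count as containment, which makes the
      contain branch of the TSD loss the (only) branch that returns 0 for a
      perfect prediction.
    """

    SEPARATED = "separated"
    INTERSECT = "intersect"
    CONTAIN = "contain"


@dataclass(frozen=True)
class Box:
    """Axis-aligned rectangle with strictly positive width and height.

    Parameters
    ----------
    x_min, y_min, x_max, y_max
        Corner coordinates in pixels, ``x_max > x_min`` and
        ``y_max > y_min``, all finite.
    """

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        coords = (self.x_min, self.y_min, self.x_max, self.y_max)
        if not all(math.isfinite(c) for c in coords):
            raise ValueError(f"box coordinates must be finite, got {coords}")
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise ValueError(
                "box must have strictly positive width and height, got "
                f"{coords}"
            )

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.x_min + self.x_max), 0.5 * (self.y_min + self.y_max))

    @classmethod
    def from_center(cls, cx: float, cy: float, w: float, h: float) -> "Box":
        """Build a box from its center point and side lengths."""
        return cls(cx - 0.5 * w, cy - 0.5 * h, cx + 0.5 * w, cy + 0.5 * h)

    def shifted(self, dx: float, dy: float) -> "Box":
        """Translate the box by ``(dx, dy)``."""
        return Box(self.x_min + dx, self.y_min + dy, self.x_max + dx, self.y_max + dy)

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.x_min, self.y_min, self.x_max, self.y_max)


def center(box: Box) -> tuple[float, float]:
    """Midpoint of the rectangle, ``((x_min+x_max)/2, (y_min+y_max)/2)``."""
    return box.center


def circumradius(box: Box) -> float:
    """Radius of the circle through the box's four corners.

    Equals half the diagonal, ``sqrt(w**2 + h**2) / 2``; all four corners are
    equidistant from the box center at exactly this radius.
    """
    return 0.5 * math.hypot(box.width, box.height)


def chebyshev_center_distance(a: Box, b: Box) -> float:
    """L-infinity distance between the two box centers.

    ``max(|cx_a - cx_b|, |cy_a - cy_b|)`` — the distance the TSD metric
    standardizes. Symmetric; zero iff the centers coincide.
    """
    (ax, ay), (bx, by) = a.center, b.center
    return max(abs(ax - bx), abs(ay - by))


def euclidean_center_distance(a: Box, b: Box) -> float:
    """L2 distance between the two box centers (always >= the Chebyshev one)."""
    (ax, ay), (bx, by) = a.center, b.center
    return math.hypot(ax - bx, ay - by)


def intersection_area(a: Box, b: Box) -> float:
    """Area of the rectangle overlap; 0 when disjoint or touching only at an
    edge or corner."""
    iw = min(a.x_max, b.x_max) - max(a.x_min, b.x_min)
    ih = min(a.y_max, b.y_max) - max(a.y_min, b.y_min)
    if iw <= 0.0 or ih <= 0.0:
        return 0.0
    return iw * ih


def union_area(a: Box, b: Box) -> float:
    """Area of the union of the two rectangles (inclusion–exclusion)."""
    return a.area + b.area - intersection_area(a, b)


def enclosing_box(a: Box, b: Box) -> Box:
    """Smallest axis-aligned box containing both inputs (the C of GIoU/DIoU)."""
    return Box(
        min(a.x_min, b.x_min),
        min(a.y_min, b.y_min),
        max(a.x_max, b.x_max),
        max(a.y_max, b.y_max),
    )


def _contains(outer: Box, inner: Box) -> bool:
    # boundary contact counts as inside
    return (
        outer.x_min <= inner.x_min
        and outer.y_min <= inner.y_min
        and outer.x_max >= inner.x_max
        and outer.y_max >= inner.y_max
    )


def classify_relationship(a: Box, b: Box) -> Relationship:
    """Classify an ordered pair into the separated/intersect/contain trichotomy.

    ``CONTAIN`` if one box lies entirely inside (or on the boundary of) the
    other — identical boxes are CONTAIN. ``INTERSECT`` if the overlap area is
    positive but neither contains the other. ``SEPARATED`` otherwise,
    including edge- or corner-touching pairs whose overlap has measure zero.
    Symmetric in its arguments.
    """
    if _contains(a, b) or _contains(b, a):
        return Relationship.CONTAIN
    if intersection_area(a, b) > 0.0:
        return Relationship.INTERSECT
    return Relationship.SEPARATED


def boxes_to_array(boxes: Iterable[Box]) -> np.ndarray:
    """Stack boxes into an ``(N, 4)`` float array of corner coordinates."""
    out = np.asarray([b.as_tuple() for b in boxes], dtype=float)
    return out.reshape(-1, 4)


def array_to_boxes(arr: Sequence[Sequence[float]] | np.ndarray) -> list[Box]:
    """Inverse of :func:`boxes_to_array`; validates every row."""
    a = np.asarray(arr, dtype=float).reshape(-1, 4)
    return [Box(*row) for row in a]
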