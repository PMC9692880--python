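"""Readers and writers for box annotations: COCO-dialect JSON and plain CSV.

Everything is converted at the boundary to the package's internal corner
convention (x_min, y_min, x_max, y_max); COCO's top-left + width/height
``bbox`` arrays are translated on read and back on write. Round-trips are
lossless: CSV floats are serialized with Python's shortest-repr formatting
(canonical and exact), COCO JSON at full float precision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .boxes import Box

__all__ = [
    "AnnotationSet",
    "read_coco",
    "write_coco",
    "read_csv_boxes",
    "write_csv_boxes",
]

CSV_REQUIRED = ("x_min", "y_min", "x_max", "y_max")


@dataclass
class AnnotationSet:
    """A flat collection of boxes with optional per-box score and category.

    ``scores`` and ``categories`` are either None or aligned with
    ``boxes``; ``iscrowd`` flags from COCO-dialect files are retained.
    """

    boxes: list[Box]
    scores: list[float] | None = None
    categories: list[int] | None = None
    iscrowd: list[int] | None = None
    image_dims: tuple[float, float] | None = None
    source_format: str = "memory"

    def __post_init__(self) -> None:
        n = len(self.boxes)
        for name in ("scores", "categories", "iscrowd"):
            v = getattr(self, name)
            if v is not None and len(v) != n:
                raise ValueError(f"{name} length {len(v)} != number of boxes {n}")

    def __len__(self) -> int:
        return len(self.boxes)


def read_coco(path: str | Path) -> AnnotationSet:
    """Read a COCO-dialect annotation file into corner-convention boxes.

    Expects the usual structure: an ``annotations`` list whose entries have
    ``bbox = [x, y, w, h]`` (top-left corner plus size), and optionally an
    ``images`` list supplying image dimensions. Category ids and iscrowd
    flags are preserved. Malformed records and zero-area bboxes are
    rejected with the offending record id in the error message.
    """
    path = Path(path)
    with open(path) as fh:
        try:
            data = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ValueError(f"{path}: not valid JSON: {exc}") from exc
    if not isinstance(data, dict) or "annotations" not in data:
        raise ValueError(f"{path}: expected an object with an 'annotations' list")

    boxes: list[Box] = []
    scores: list[float] = []
    categories: list[int] = []
    iscrowd: list[int] = []
    any_score = False
    for rec in data["annotations"]:
        rec_id = rec.get("id", "<no id>") if isinstance(rec, dict) else "<not a dict>"
        if not isinstance(rec, dict) or "bbox" not in rec or len(rec["bbox"]) != 4:
            raise ValueError(f"{path}: annotation {rec_id}: missing or malformed 'bbox'")
        x, y, w, h = (float(v) for v in rec["bbox"])
        if w <= 0 or h <= 0:
            raise ValueError(
                f"{path}: annotation {rec_id}: zero-area bbox [x={x}, y={y}, w={w}, h={h}]"
            )
        boxes.append(Box(x, y, x + w, y + h))
        categories.append(int(rec.get("category_id", 0)))
        iscrowd.append(int(rec.get("iscrowd", 0)))
        if "score" in rec:
            any_score = True
            scores.append(float(rec["score"]))
        else:
            scores.append(1.0)

    dims = None
    images = data.get("images") or []
    if images and "width" in images[0] and "height" in images[0]:
        dims = (float(images[0]["width"]), float(images[0]["height"]))
    return AnnotationSet(
        boxes=boxes,
        scores=scores if any_score else None,
        categories=categories,
        iscrowd=iscrowd,
        image_dims=dims,
        source_format="coco",
    )


def write_coco(ann: AnnotationSet, path: str | Path) -> None:
    """Write an AnnotationSet as a COCO-dialect file (bbox = [x, y, w, h])."""
    path = Path(path)
    annotations = []
    for i, b in enumerate(ann.boxes):
        rec: dict = {
            "id": i + 1,
            "image_id": 1,
            "bbox": [b.x_min, b.y_min, b.width, b.height],
            "area": b.area,
            "category_id": ann.categories[i] if ann.categories else 0,
            "iscrowd": ann.iscrowd[i] if ann.iscrowd else 0,
        }
        if ann.scores is not None:
            rec["score"] = ann.scores[i]
        annotations.append(rec)
    images = []
    if ann.image_dims is not None:
        images = [{"id": 1, "width": ann.image_dims[0], "height": ann.image_dims[1]}]
    with open(path, "w") as fh:
        json.dump({"images": images, "annotations": annotations, "categories": []}, fh)


def read_csv_boxes(path: str | Path) -> AnnotationSet:
    """Read boxes from a CSV with header x_min,y_min,x_max,y_max[,score][,category]."""
    import csv

    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ValueError(f"{path}: empty file, expected a header row")
        missing = [c for c in CSV_REQUIRED if c not in reader.fieldnames]
        if missing:
            raise ValueError(f"{path}: missing required columns: {missing}")
        has_score = "score" in reader.fieldnames
        has_cat = "category" in reader.fieldnames
        boxes, scores, cats = [], [], []
        for row in reader:
            boxes.append(
                Box(
                    float(row["x_min"]),
                    float(row["y_min"]),
                    float(row["x_max"]),
                    float(row["y_max"]),
                )
            )
            if has_score:
                scores.append(float(row["score"]))
            if has_cat:
                cats.append(int(row["category"]))
    return AnnotationSet(
        boxes=boxes,
        scores=scores if has_score else None,
        categories=cats if has_cat else None,
        source_format="csv",
    )


def write_csv_boxes(ann: AnnotationSet, path: str | Path) -> None:
    """Write boxes to CSV, losslessly (shortest-repr float formatting)."""
    import csv

    path = Path(path)
    header = list(CSV_REQUIRED)
    if ann.scores is not None:
        header.append("score")
    if ann.categories is not None:
        header.append("category")
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for i, b in enumerate(ann.boxes):
            row: list = [repr(float(v)) for v in b.as_tuple()]
            if ann.scores is not None:
                row.append(repr(float(ann.scores[i])))
            if ann.categories is not None:
                row.append(int(ann.categories[i]))
            writer.writerow(row)
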