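"""Bounding boxes, candidate regions, IoU merging, and patch cropping.

Boxes are axis-aligned, half-open in both axes: a box (x, y, w, h) covers
[x, x+w) x [y, y+h) in (column, row) pixel coordinates, 0-based.  Overlapping
candidates produced by template matching are merged (union box) whenever
their intersection-over-union exceeds a threshold, 0.3 by default.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.transform import resize as _sk_resize

__all__ = [
    "BoundingBox",
    "Candidate",
    "iou",
    "merge_candidates",
    "crop_patch",
    "save_candidates_csv",
    "load_candidates_csv",
    "save_candidates_json",
    "load_candidates_json",
]

PATCH_SIZE = (200, 200)


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box: x = left, y = top, w = width, h = height (pixels)."""

    x: float
    y: float
    w: float
    h: float

    def __post_init__(self):
        if not (self.w > 0 and self.h > 0):
            raise ValueError(f"box must have positive size, got w={self.w}, h={self.h}")

    @property
    def x2(self) -> float:
        return self.x + self.w

    @property
    def y2(self) -> float:
        return self.y + self.h

    @property
    def center(self) -> tuple[float, float]:
        return (self.x + self.w / 2.0, self.y + self.h / 2.0)

    @property
    def area(self) -> float:
        return self.w * self.h

    @classmethod
    def from_center(cls, cx: float, cy: float, w: float, h: float) -> "BoundingBox":
        return cls(cx - w / 2.0, cy - h / 2.0, w, h)

    def union(self, other: "BoundingBox") -> "BoundingBox":
        """Smallest box containing both."""
        x1 = min(self.x, other.x)
        y1 = min(self.y, other.y)
        return BoundingBox(x1, y1, max(self.x2, other.x2) - x1, max(self.y2, other.y2) - y1)

    def clip(self, width: float, height: float) -> "BoundingBox":
        """Clip to the image rectangle [0, width) x [0, height)."""
        x1 = min(max(self.x, 0.0), width)
        y1 = min(max(self.y, 0.0), height)
        x2 = min(max(self.x2, 0.0), width)
        y2 = min(max(self.y2, 0.0), height)
        if x2 <= x1 or y2 <= y1:
            raise ValueError("box lies fully outside the image")
        return BoundingBox(x1, y1, x2 - x1, y2 - y1)


@dataclass(frozen=True)
class Candidate:
    """A suspected mass region: box plus matching degree and, once the
    classifier has run, a mass probability."""

    box: BoundingBox
    degree: float = 0.0
    probability: float | None = None

    def __post_init__(self):
        if not (0.0 <= self.degree <= 1.0):
            raise ValueError(f"degree must be in [0,1], got {self.degree}")
        if self.probability is not None and not (0.0 <= self.probability <= 1.0):
            raise ValueError(f"probability must be in [0,1], got {self.probability}")


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection-over-union of two boxes, in [0, 1]."""
    ix = max(0.0, min(a.x2, b.x2) - max(a.x, b.x))
    iy = max(0.0, min(a.y2, b.y2) - max(a.y, b.y))
    inter = ix * iy
    if inter == 0.0:
        return 0.0
    return inter / (a.area + b.area - inter)


def _merge_key(c: Candidate):
    return (-c.degree, c.box.x, c.box.y)


def merge_candidates(candidates: list[Candidate], iou_threshold: float = 0.3) -> list[Candidate]:
    """Merge overlapping candidates to a fixpoint.

    Repeatedly merges the pair with the highest IoU strictly above
    ``iou_threshold`` into their union box (degree = max of the pair) until
    every remaining pair has IoU <= threshold.  Ties are broken by
    (degree desc, x, y) so the result is deterministic and independent of
    input order.  The union of the output boxes covers the union of the
    input boxes.
    """
    if not (0.0 <= iou_threshold <= 1.0):
        raise ValueError("iou_threshold must be in [0,1]")
    pool = sorted(candidates, key=_merge_key)
    while len(pool) > 1:
        best = None
        best_iou = iou_threshold
        for i in range(len(pool)):
            for j in range(i + 1, len(pool)):
                v = iou(pool[i].box, pool[j].box)
                if v > best_iou:
                    best_iou = v
                    best = (i, j)
        if best is None:
            break
        i, j = best
        a, b = pool[i], pool[j]
        merged = Candidate(
            box=a.box.union(b.box),
            degree=max(a.degree, b.degree),
            probability=None,
        )
        pool = [c for k, c in enumerate(pool) if k not in (i, j)]
        pool.append(merged)
        pool.sort(key=_merge_key)
    return pool


def crop_patch(
    image: np.ndarray,
    box: BoundingBox,
    out_size: tuple[int, int] = PATCH_SIZE,
) -> np.ndarray:
    """Crop ``box`` from ``image`` (clipped to its bounds) and resize to
    ``out_size`` (height, width) with bilinear interpolation.

    Returns float32; intensity values keep the input's scale.  A crop whose
    size already equals ``out_size`` is returned as an exact copy.
    """
    arr = np.asarray(image)
    if arr.ndim != 2:
        raise ValueError("image must be 2-D grayscale")
    h, w = arr.shape
    clipped = box.clip(w, h)  # raises if fully outside
    x1 = int(np.floor(clipped.x))
    y1 = int(np.floor(clipped.y))
    x2 = int(np.ceil(clipped.x2))
    y2 = int(np.ceil(clipped.y2))
    patch = arr[y1:y2, x1:x2].astype(np.float32)
    if patch.shape == tuple(out_size):
        return patch.copy()
    out = _sk_resize(patch, out_size, order=1, preserve_range=True, anti_aliasing=False)
    return out.astype(np.float32)


# ---------------------------------------------------------------------------
# serialization

_CSV_FIELDS = ["image_id", "x", "y", "w", "h", "degree", "probability"]


def _candidate_row(image_id: str, c: Candidate) -> dict:
    return {
        "image_id": image_id,
        "x": c.box.x,
        "y": c.box.y,
        "w": c.box.w,
        "h": c.box.h,
        "degree": c.degree,
        "probability": "" if c.probability is None else c.probability,
    }


def save_candidates_csv(path: str | Path, records: list[tuple[str, Candidate]]) -> None:
    """Write (image_id, candidate) records as CSV in corner (x, y, w, h) form."""
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=_CSV_FIELDS)
        writer.writeheader()
        for image_id, cand in records:
            writer.writerow(_candidate_row(image_id, cand))


def load_candidates_csv(path: str | Path, fmt: str = "corner") -> list[tuple[str, Candidate]]:
    """Read candidates from CSV.  ``fmt`` is "corner" (x = left, y = top) or
    "center" (x, y are the box centre)."""
    if fmt not in ("corner", "center"):
        raise ValueError("fmt must be 'corner' or 'center'")
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            x, y, w, h = (float(row[k]) for k in ("x", "y", "w", "h"))
            if fmt == "center":
                box = BoundingBox.from_center(x, y, w, h)
            else:
                box = BoundingBox(x, y, w, h)
            prob = row.get("probability", "")
            out.append(
                (
                    row["image_id"],
                    Candidate(
                        box=box,
                        degree=float(row.get("degree", 0.0) or 0.0),
                        probability=float(prob) if prob not in ("", None) else None,
                    ),
                )
            )
    return out


def save_candidates_json(path: str | Path, records: list[tuple[str, Candidate]]) -> None:
    data = [_candidate_row(image_id, c) for image_id, c in records]
    for row in data:
        if row["probability"] == "":
            row["probability"] = None
    Path(path).write_text(json.dumps(data, indent=2))


def load_candidates_json(path: str | Path, fmt: str = "corner") -> list[tuple[str, Candidate]]:
    if fmt not in ("corner", "center"):
        raise ValueError("fmt must be 'corner' or 'center'")
    out = []
    for row in json.loads(Path(path).read_text()):
        x, y, w, h = (float(row[k]) for k in ("x", "y", "w", "h"))
        box = BoundingBox.from_center(x, y, w, h) if fmt == "center" else BoundingBox(x, y, w, h)
        prob = row.get("probability")
        out.append(
            (
                row["image_id"],
                Candidate(box=box, degree=float(row.get("degree") or 0.0),
                          probability=None if prob is None else float(prob)),
            )
        )
    return out
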