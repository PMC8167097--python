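"""Geometry primitives and dataset containers.

Boxes use a 0-based, half-open pixel convention: a box occupies the
columns ``[x_min, x_max)`` and rows ``[y_min, y_max)``, so its area is
``(x_max - x_min) * (y_max - y_min)``.  Annotation formats that use a
different on-disk dialect (1-based inclusive Pascal VOC, normalized
YOLO) are converted at the I/O boundary, never here.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Literal, Optional, Sequence, Union

import numpy as np

__all__ = [
    "BoundingBox",
    "ScoredDetection",
    "ImageRecord",
    "Dataset",
    "LabelKind",
    "iou",
    "clip_box",
]

LabelKind = Literal["ground_truth", "pseudo", "unlabeled"]


class EmptyBoxError(ValueError):
    """A box degenerated to zero area (bad input or clipped away)."""


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned rectangle in pixel units, half-open on both axes.

    Parameters
    ----------
    x_min, y_min
        Top-left corner (column, row).
    x_max, y_max
        Exclusive bottom-right corner.
    class_label
        Category name.  The pipeline is single-class ("fruit") but the
        field keeps the mean-over-classes mAP well defined.
    """

    x_min: float
    y_min: float
    x_max: float
    y_max: float
    class_label: str = "fruit"

    def __post_init__(self) -> None:
        coords = (self.x_min, self.y_min, self.x_max, self.y_max)
        if not all(np.isfinite(c) for c in coords):
            raise ValueError(f"non-finite box coordinates {coords}")
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise EmptyBoxError(f"zero-area box {coords}")
        # negative coordinates are tolerated before clipping (e.g. a box
        # read from a file that overhangs the frame); clip_box restores
        # the in-frame invariant

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height


@dataclass(frozen=True)
class ScoredDetection:
    """A detector output: box plus confidence score in [0, 1]."""

    box: BoundingBox
    score: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.score <= 1.0):
            raise ValueError(f"score {self.score} outside [0, 1]")


@dataclass
class ImageRecord:
    """One image with optional ground-truth and/or pseudo annotations.

    ``pixels`` may hold an H×W×3 uint8 array, a file path to load
    lazily, or None when only annotations matter.
    """

    image_id: str
    pixels: Union[np.ndarray, Path, str, None] = None
    annotations: list[BoundingBox] = field(default_factory=list)
    pseudo_labels: list[ScoredDetection] = field(default_factory=list)

    def load_pixels(self) -> np.ndarray:
        """Return the H×W×3 uint8 array, reading from disk if needed."""
        if isinstance(self.pixels, np.ndarray):
            return self.pixels
        if self.pixels is None:
            raise ValueError(f"record {self.image_id!r} has no pixel data")
        from PIL import Image

        with Image.open(self.pixels) as im:
            return np.asarray(im.convert("RGB"))

    def image_size(self) -> tuple[int, int]:
        """(width, height) in pixels."""
        arr = self.load_pixels()
        return arr.shape[1], arr.shape[0]


@dataclass
class Dataset:
    """Ordered collection of :class:`ImageRecord`.

    ``labeled`` says what the annotations mean: ``"ground_truth"``
    (manual/exact boxes), ``"pseudo"`` (machine-generated, scored), or
    ``"unlabeled"`` (no usable annotations).
    """

    records: list[ImageRecord] = field(default_factory=list)
    labeled: LabelKind = "unlabeled"

    def __post_init__(self) -> None:
        ids = [r.image_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate image_ids in dataset: {dupes}")
        if self.labeled == "unlabeled":
            bad = [r.image_id for r in self.records if r.annotations]
            if bad:
                raise ValueError(
                    f"unlabeled dataset carries ground-truth boxes on {bad}"
                )

    @property
    def size(self) -> int:
        return len(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ImageRecord]:
        return iter(self.records)

    def __getitem__(self, key: int) -> ImageRecord:
        return self.records[key]

    def by_id(self, image_id: str) -> ImageRecord:
        for r in self.records:
            if r.image_id == image_id:
                return r
        raise KeyError(image_id)


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection-over-union of two boxes; 0 when disjoint."""
    ix = min(a.x_max, b.x_max) - max(a.x_min, b.x_min)
    iy = min(a.y_max, b.y_max) - max(a.y_min, b.y_min)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    union = a.area + b.area - inter
    return inter / union


def clip_box(box: BoundingBox, width: float, height: float) -> BoundingBox:
    """Clamp a box to the image frame [0, width) × [0, height).

    Raises
    ------
    EmptyBoxError
        If the box lies fully outside the frame (zero area after clip).
    """
    if width <= 0 or height <= 0:
        raise ValueError("image dimensions must be positive")
    x0 = min(max(box.x_min, 0.0), width)
    y0 = min(max(box.y_min, 0.0), height)
    x1 = min(max(box.x_max, 0.0), width)
    y1 = min(max(box.y_max, 0.0), height)
    if x0 >= x1 or y0 >= y1:
        raise EmptyBoxError(
            f"box ({box.x_min},{box.y_min},{box.x_max},{box.y_max}) "
            f"empty after clipping to {width}x{height}"
        )
    return replace(box, x_min=x0, y_min=y0, x_max=x1, y_max=y1)
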