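"""Geometry primitives and the annotation data model.

Boxes are axis-aligned rectangles in 0-based pixel coordinates, half-open on
both axes: pixel column ``x`` belongs to a box iff ``x0 <= x < x1``.  Annotation
boxes are integer-valued so that areas and overlaps are exact pixel counts;
model-internal boxes (proposals, regressed boxes) may be fractional and live
outside this module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Optional, Union

import numpy as np


class Source(str, Enum):
    """Provenance of an annotation: captured in the image, or pasted by augmentation."""

    ORIGINAL = "original"
    PASTED = "pasted"


@dataclass(frozen=True)
class Box:
    """Axis-aligned rectangle, 0-based half-open pixel coordinates."""

    x0: int
    y0: int
    x1: int
    y1: int

    def __post_init__(self) -> None:
        if not (self.x1 > self.x0 and self.y1 > self.y0):
            raise ValueError(
                f"box must have positive extent, got ({self.x0},{self.y0},{self.x1},{self.y1})"
            )

    @property
    def width(self) -> int:
        return self.x1 - self.x0

    @property
    def height(self) -> int:
        return self.y1 - self.y0

    @property
    def area(self) -> int:
        return self.width * self.height

    def translated(self, dx: int, dy: int) -> "Box":
        return Box(self.x0 + dx, self.y0 + dy, self.x1 + dx, self.y1 + dy)

    def contains_box(self, other: "Box") -> bool:
        return (
            other.x0 >= self.x0
            and other.y0 >= self.y0
            and other.x1 <= self.x1
            and other.y1 <= self.y1
        )

    # -- COCO xywh dialect -------------------------------------------------
    def to_xywh(self) -> list:
        return [self.x0, self.y0, self.width, self.height]

    @classmethod
    def from_xywh(cls, x: float, y: float, w: float, h: float) -> "Box":
        return cls(int(x), int(y), int(x) + int(w), int(y) + int(h))


def box_intersection_area(a: Box, b: Box) -> int:
    """Exact pixel area of ``a ∩ b`` (0 for disjoint or merely touching boxes)."""
    iw = min(a.x1, b.x1) - max(a.x0, b.x0)
    ih = min(a.y1, b.y1) - max(a.y0, b.y0)
    if iw <= 0 or ih <= 0:
        return 0
    return iw * ih


def box_union_area(a: Box, b: Box) -> int:
    return a.area + b.area - box_intersection_area(a, b)


def iou(a: Box, b: Box) -> float:
    """Intersection over union of two boxes, in [0, 1]."""
    inter = box_intersection_area(a, b)
    if inter == 0:
        return 0.0
    return inter / box_union_area(a, b)


@dataclass(frozen=True)
class Annotation:
    """A labelled box.  class_id 0 = psyllid, 1 = fruit fly by convention."""

    box: Box
    class_id: int
    source: Source = Source.ORIGINAL


DEFAULT_CATEGORIES = {0: "psyllid", 1: "fruit fly"}


class ForegroundMask:
    """Binary partition of an image into inner (leaves/trunk, 1) and outer
    (segmentation-removed background, 0) regions.

    The outer-region area — the count of 0 pixels — is the denominator of the
    outer-overlap rate used by the paste constraint.
    """

    def __init__(self, values: np.ndarray):
        values = np.asarray(values)
        if values.ndim != 2:
            raise ValueError(f"mask must be 2-D, got shape {values.shape}")
        self.values = values.astype(bool)

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    @property
    def area_outer(self) -> int:
        return int((~self.values).sum())

    @property
    def area_inner(self) -> int:
        return int(self.values.sum())

    def __eq__(self, other) -> bool:
        return isinstance(other, ForegroundMask) and np.array_equal(self.values, other.values)

    @classmethod
    def from_png(cls, path: Union[str, Path]) -> "ForegroundMask":
        from PIL import Image

        arr = np.asarray(Image.open(path).convert("L"))
        return cls(arr >= 128)

    def to_png(self, path: Union[str, Path]) -> None:
        from PIL import Image

        Image.fromarray((self.values.astype(np.uint8)) * 255).save(path)


@dataclass
class DatasetRecord:
    """One image with its annotations and optional foreground mask.

    ``image`` is either an in-memory ``uint8`` HxWx3 array or a file path;
    ``width``/``height`` are always known without loading pixels.
    """

    record_id: int
    image: Union[np.ndarray, str, Path]
    width: int
    height: int
    annotations: list = field(default_factory=list)
    mask: Optional[ForegroundMask] = None
    file_name: Optional[str] = None
    mask_file_name: Optional[str] = None

    def load_image(self, root: Union[str, Path, None] = None) -> np.ndarray:
        if isinstance(self.image, np.ndarray):
            return self.image
        from PIL import Image

        path = Path(self.image)
        if root is not None and not path.is_absolute():
            path = Path(root) / path
        arr = np.asarray(Image.open(path).convert("RGB"))
        if (arr.shape[0], arr.shape[1]) != (self.height, self.width):
            warnings.warn(
                f"record {self.record_id}: image file is {arr.shape[1]}x{arr.shape[0]} "
                f"but record declares {self.width}x{self.height}"
            )
        return arr

    @property
    def n_original(self) -> int:
        """Number of original (non-pasted) samples in this record."""
        return sum(1 for a in self.annotations if a.source == Source.ORIGINAL)

    def validate(self) -> None:
        img_box = Box(0, 0, self.width, self.height)
        for a in self.annotations:
            if not img_box.contains_box(a.box):
                raise ValueError(
                    f"record {self.record_id}: annotation box {a.box} exceeds "
                    f"image bounds {self.width}x{self.height}"
                )
        if self.mask is not None and (self.mask.height, self.mask.width) != (
            self.height,
            self.width,
        ):
            raise ValueError(
                f"record {self.record_id}: mask {self.mask.width}x{self.mask.height} "
                f"does not match image {self.width}x{self.height}"
            )


@dataclass
class DetectionDataset:
    """Images + per-image annotation lists + optional masks."""

    records: list
    categories: dict = field(default_factory=lambda: dict(DEFAULT_CATEGORIES))
    root: Optional[Path] = None

    def __len__(self) -> int:
        return len(self.records)

    @property
    def n_annotations(self) -> int:
        return sum(len(r.annotations) for r in self.records)

    def validate(self) -> None:
        for r in self.records:
            r.validate()
            for a in r.annotations:
                if a.class_id not in self.categories:
                    raise ValueError(
                        f"record {r.record_id}: class_id {a.class_id} not in "
                        f"declared categories {sorted(self.categories)}"
                    )

    def copy_shallow(self) -> "DetectionDataset":
        recs = [replace(r, annotations=list(r.annotations)) for r in self.records]
        return DetectionDataset(records=recs, categories=dict(self.categories), root=self.root)
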