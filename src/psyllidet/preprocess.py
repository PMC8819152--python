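"""Training-time preprocessing for high-resolution field imagery.

Camera frames (up to 4000x5000 px) are far larger than a detector input, and
naive downscaling erases targets that are only a handful of pixels wide.  The
pipeline therefore (1) crops each frame into a 3x3 grid of tiles with
annotations remapped into tile coordinates, (2) randomly picks one of two
training scales per sample, resizing with preserved aspect ratio, and
(3) rotates each sample with 50% probability.  Rotations are restricted to
multiples of 90 degrees so axis-aligned boxes remap exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from skimage.transform import resize as _sk_resize

from .boxes import Annotation, Box

__all__ = [
    "TileGrid",
    "Tile",
    "ScaleSpec",
    "tile_image",
    "reassemble_tiles",
    "choose_scale",
    "multiscale_resize",
    "random_rotate",
    "rotate_box",
]


@dataclass(frozen=True)
class TileGrid:
    """A rows x cols partition of a parent image into disjoint tiles.

    Boundaries are floor-divided; the last row/column absorbs any remainder,
    so the tiles always cover the parent exactly.
    """

    rows: int = 3
    cols: int = 3

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError("grid must have at least one row and column")

    def extents(self, width: int, height: int) -> List[Box]:
        """Tile boxes in row-major order."""
        if width < self.cols or height < self.rows:
            raise ValueError(
                f"image {width}x{height} smaller than a {self.rows}x{self.cols} grid"
            )
        # floor-division boundaries; last row/col absorbs the remainder
        xs = [0] + [(width // self.cols) * (c + 1) for c in range(self.cols - 1)] + [width]
        ys = [0] + [(height // self.rows) * (r + 1) for r in range(self.rows - 1)] + [height]
        return [
            Box(xs[c], ys[r], xs[c + 1], ys[r + 1])
            for r in range(self.rows)
            for c in range(self.cols)
        ]


@dataclass
class Tile:
    """One crop of a parent image with remapped annotations."""

    image: np.ndarray
    annotations: List[Annotation]
    extent: Box  # location in parent coordinates
    index: Tuple[int, int]  # (row, col)


def tile_image(
    image: np.ndarray,
    annotations: Sequence[Annotation],
    grid: Optional[TileGrid] = None,
    keep_fraction: float = 0.5,
) -> List[Tile]:
    """Crop ``image`` into ``grid`` tiles (default 3x3 = nine blocks).

    Parent boxes are translated into tile coordinates and clipped to the tile;
    a clipped box is retained iff its clipped area is at least
    ``keep_fraction`` times the original area (and positive), which drops
    targets that are mostly outside the tile.  Tiles reassemble to the parent
    bit-exactly.
    """
    grid = grid or TileGrid()
    if not 0.0 <= keep_fraction <= 1.0:
        raise ValueError("keep_fraction must be in [0, 1]")
    image = np.asarray(image)
    h, w = image.shape[:2]
    tiles = []
    for i, extent in enumerate(grid.extents(w, h)):
        r, c = divmod(i, grid.cols)
        tile_anns = []
        for a in annotations:
            ix0 = max(a.box.x0, extent.x0)
            iy0 = max(a.box.y0, extent.y0)
            ix1 = min(a.box.x1, extent.x1)
            iy1 = min(a.box.y1, extent.y1)
            if ix1 <= ix0 or iy1 <= iy0:
                continue
            clipped_area = (ix1 - ix0) * (iy1 - iy0)
            if clipped_area < keep_fraction * a.box.area or clipped_area == 0:
                continue
            local = Box(ix0 - extent.x0, iy0 - extent.y0, ix1 - extent.x0, iy1 - extent.y0)
            tile_anns.append(Annotation(box=local, class_id=a.class_id, source=a.source))
        tiles.append(
            Tile(
                image=image[extent.y0 : extent.y1, extent.x0 : extent.x1].copy(),
                annotations=tile_anns,
                extent=extent,
                index=(r, c),
            )
        )
    return tiles


def reassemble_tiles(tiles: Sequence[Tile]) -> np.ndarray:
    """Stitch tiles back into the parent image (inverse of :func:`tile_image`)."""
    if not tiles:
        raise ValueError("no tiles to reassemble")
    w = max(t.extent.x1 for t in tiles)
    h = max(t.extent.y1 for t in tiles)
    sample = tiles[0].image
    shape = (h, w) + sample.shape[2:]
    out = np.zeros(shape, dtype=sample.dtype)
    for t in tiles:
        out[t.extent.y0 : t.extent.y1, t.extent.x0 : t.extent.x1] = t.image
    return out


@dataclass(frozen=True)
class ScaleSpec:
    """Ordered multiscale training scales as (long-side cap, short-side target)."""

    scales: Tuple[Tuple[int, int], ...] = ((1500, 1000), (1333, 800))

    def __post_init__(self) -> None:
        if not self.scales:
            raise ValueError("scale spec must be non-empty")
        for long_cap, short_target in self.scales:
            if not (long_cap >= short_target > 0):
                raise ValueError(
                    f"scale pair must satisfy long >= short > 0, got ({long_cap}, {short_target})"
                )


def choose_scale(
    spec: Optional[ScaleSpec] = None, rng: Optional[np.random.Generator] = None
) -> Tuple[int, int]:
    """Uniformly draw one (long-cap, short-target) pair from the spec."""
    spec = spec or ScaleSpec()
    rng = rng if rng is not None else np.random.default_rng()
    return spec.scales[int(rng.integers(0, len(spec.scales)))]


def multiscale_resize(
    image: np.ndarray,
    annotations: Sequence[Annotation],
    spec: Optional[ScaleSpec] = None,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[np.ndarray, List[Annotation], Tuple[int, int]]:
    """Resize to one uniformly chosen training scale, preserving aspect ratio.

    The short side is scaled to the short-side target unless that would push
    the long side past the cap, in which case the long side is set to the cap.
    Boxes scale by the same factor (rounded to integer pixels).  Returns
    ``(resized image, scaled annotations, chosen scale pair)``.
    """
    spec = spec or ScaleSpec()
    rng = rng if rng is not None else np.random.default_rng()
    image = np.asarray(image)
    h, w = image.shape[:2]

    long_cap, short_target = choose_scale(spec, rng)
    short_side = min(h, w)
    long_side = max(h, w)
    factor = short_target / short_side
    if long_side * factor > long_cap:
        factor = long_cap / long_side

    # half-up rounding: 666.5 px -> 667, matching the documented resize rule
    new_h = int(np.floor(h * factor + 0.5))
    new_w = int(np.floor(w * factor + 0.5))
    resized = _sk_resize(image, (new_h, new_w), preserve_range=True, anti_aliasing=factor < 1)
    resized = resized.astype(image.dtype)

    scaled = []
    for a in annotations:
        x0 = int(np.floor(a.box.x0 * factor + 0.5))
        y0 = int(np.floor(a.box.y0 * factor + 0.5))
        x1 = max(x0 + 1, int(np.floor(a.box.x1 * factor + 0.5)))
        y1 = max(y0 + 1, int(np.floor(a.box.y1 * factor + 0.5)))
        scaled.append(
            Annotation(
                box=Box(min(x0, new_w - 1), min(y0, new_h - 1), min(x1, new_w), min(y1, new_h)),
                class_id=a.class_id,
                source=a.source,
            )
        )
    return resized, scaled, (long_cap, short_target)


def rotate_box(box: Box, width: int, height: int, k: int) -> Box:
    """Remap a box under a rotation by ``k`` * 90 degrees counter-clockwise
    of a ``width`` x ``height`` image (matching ``np.rot90``)."""
    k = k % 4
    if k == 0:
        return box
    if k == 1:  # (x, y) -> (y, width - 1 - x); image becomes height W x width H
        return Box(box.y0, width - box.x1, box.y1, width - box.x0)
    if k == 2:
        return Box(width - box.x1, height - box.y1, width - box.x0, height - box.y0)
    # k == 3
    return Box(height - box.y1, box.x0, height - box.y0, box.x1)


def random_rotate(
    image: np.ndarray,
    annotations: Sequence[Annotation],
    p: float = 0.5,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[np.ndarray, List[Annotation], bool]:
    """With probability ``p``, rotate by 90/180/270 degrees (uniform) and remap
    boxes exactly; otherwise return the input unchanged.

    Returns ``(image, annotations, applied)``.  Right-angle rotations keep
    axis-aligned boxes axis-aligned, so the remap is lossless.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    rng = rng if rng is not None else np.random.default_rng()
    image = np.asarray(image)
    if rng.random() >= p:
        return image, list(annotations), False
    k = int(rng.integers(1, 4))
    h, w = image.shape[:2]
    rotated = np.rot90(image, k=k).copy()
    remapped = [
        Annotation(box=rotate_box(a.box, w, h, k), class_id=a.class_id, source=a.source)
        for a in annotations
    ]
    return rotated, remapped, True
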