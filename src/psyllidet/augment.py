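"""Small-target number enhancement by zero-overlap constrained copy-paste.

Sparse per-image target counts starve a two-stage detector of positive ROIs.
This module raises the per-image count by copying existing target crops to new
locations on the segmented foreground (leaves/trunk), subject to two
pixel-exact overlap rates both being zero for every accepted paste:

* outer-overlap rate ``u_outer`` — area of the pasted box falling on the
  segmentation-removed background, divided by the total background area;
* sample-overlap rate ``u_samples`` — area of the pasted box falling on
  pixels already occupied by target boxes, divided by the summed area of
  those boxes.

``u_outer = 0`` keeps pasted insects on plausible substrate; ``u_samples = 0``
keeps them off existing (and previously pasted) targets.  Placement is seeded
rejection sampling over top-left positions; enhanced datasets are then
duplicated by offline resampling so that downstream stochastic preprocessing
yields distinct training samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Callable, Iterable, Optional, Sequence

import numpy as np

from .boxes import (
    Annotation,
    Box,
    DatasetRecord,
    DetectionDataset,
    ForegroundMask,
    Source,
)

__all__ = [
    "OverlapReport",
    "PasteConfig",
    "PasteOutcome",
    "InfeasiblePlacementError",
    "ThresholdSegmenter",
    "segment_foreground",
    "overlap_report",
    "propose_paste_location",
    "copy_paste_augment",
    "offline_resample",
]


# --------------------------------------------------------------------------
# Segmentation interface
# --------------------------------------------------------------------------

class ThresholdSegmenter:
    """Deterministic colour/intensity threshold segmenter.

    A pixel is classified as inner (foreground: leaves, trunk) iff its green
    channel is at least as large as both other channels AND its luminance
    (mean of R, G, B) is at least ``min_luminance``.  This is a documented
    stand-in for a trained semantic segmenter; user-supplied masks always
    take precedence over it.
    """

    def __init__(self, min_luminance: float = 50.0):
        self.min_luminance = min_luminance

    def __call__(self, image: np.ndarray) -> ForegroundMask:
        img = np.asarray(image)
        if img.size == 0:
            raise ValueError("cannot segment an empty image")
        if img.ndim == 2:
            img = np.stack([img] * 3, axis=-1)
        img = img.astype(np.float64)
        r, g, b = img[..., 0], img[..., 1], img[..., 2]
        greenish = (g >= r) & (g >= b)
        bright = img[..., :3].mean(axis=-1) >= self.min_luminance
        return ForegroundMask(greenish & bright)


def segment_foreground(
    image: np.ndarray,
    segmenter: Optional[Callable[[np.ndarray], ForegroundMask]] = None,
    mask: Optional[ForegroundMask] = None,
) -> ForegroundMask:
    """Return a foreground mask for ``image``.

    A user-supplied ``mask`` always overrides the segmenter; otherwise the
    (pluggable) ``segmenter`` runs, defaulting to :class:`ThresholdSegmenter`.
    Warns when the result contains no foreground at all, since then no paste
    location can exist.
    """
    img = np.asarray(image)
    if img.size == 0:
        raise ValueError("cannot segment an empty image")
    if mask is not None:
        if (mask.height, mask.width) != img.shape[:2]:
            raise ValueError(
                f"supplied mask {mask.width}x{mask.height} does not match "
                f"image {img.shape[1]}x{img.shape[0]}"
            )
        result = mask
    else:
        result = (segmenter or ThresholdSegmenter())(img)
    if result.area_inner == 0:
        warnings.warn("segmentation produced an all-background mask; no paste locations exist")
    return result


# --------------------------------------------------------------------------
# Overlap rates
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class OverlapReport:
    """Pixel-exact overlap rates of a candidate paste box.

    ``u_outer`` is the overlap rate with the outer (removed-background)
    region; ``u_samples`` the overlap rate with existing sample boxes.  The
    paste constraint accepts a location iff both are exactly zero.
    """

    u_outer: float
    u_samples: float
    area_copy: int
    area_outer: int
    area_samples: int
    outer_undefined: bool = False   # area_outer == 0; u_outer reported as 0
    samples_undefined: bool = False  # no existing samples; u_samples reported as 0


def overlap_report(
    copy_box: Box, mask: ForegroundMask, existing: Sequence[Box]
) -> OverlapReport:
    """Compute the outer-region and sample overlap rates of ``copy_box``.

    Both rates are counted per pixel: the numerator of ``u_outer`` is the
    number of outer-region (0) mask pixels under the box; the numerator of
    ``u_samples`` is the number of pixels under the box covered by the union
    of ``existing`` boxes, while its denominator is the sum of the individual
    box areas.
    """
    img_box = Box(0, 0, mask.width, mask.height)
    if not img_box.contains_box(copy_box):
        raise ValueError(f"copy box {copy_box} exceeds mask bounds {mask.width}x{mask.height}")

    window = mask.values[copy_box.y0 : copy_box.y1, copy_box.x0 : copy_box.x1]
    outer_hits = int((~window).sum())
    area_outer = mask.area_outer
    outer_undefined = area_outer == 0
    u_outer = 0.0 if outer_undefined else outer_hits / area_outer

    area_samples = sum(b.area for b in existing)
    samples_undefined = area_samples == 0
    if samples_undefined:
        u_samples = 0.0
    else:
        occupancy = np.zeros((mask.height, mask.width), dtype=bool)
        for b in existing:
            occupancy[b.y0 : b.y1, b.x0 : b.x1] = True
        sample_hits = int(
            occupancy[copy_box.y0 : copy_box.y1, copy_box.x0 : copy_box.x1].sum()
        )
        u_samples = sample_hits / area_samples

    return OverlapReport(
        u_outer=u_outer,
        u_samples=u_samples,
        area_copy=copy_box.area,
        area_outer=area_outer,
        area_samples=area_samples,
        outer_undefined=outer_undefined,
        samples_undefined=samples_undefined,
    )


# --------------------------------------------------------------------------
# Placement search
# --------------------------------------------------------------------------

class InfeasiblePlacementError(ValueError):
    """No placement of the requested size can satisfy the zero-overlap
    constraint anywhere in the image — failure is guaranteed, not random."""


def _free_pixels(mask: ForegroundMask, existing: Sequence[Box]) -> np.ndarray:
    free = mask.values.copy()
    for b in existing:
        free[b.y0 : b.y1, b.x0 : b.x1] = False
    return free


def _feasible_positions(free: np.ndarray, w: int, h: int) -> np.ndarray:
    """Boolean grid over top-left positions where a w x h box covers only
    free pixels, via a summed-area table (exact, no tolerance)."""
    H, W = free.shape
    if h > H or w > W:
        return np.zeros((0, 0), dtype=bool)
    sat = np.zeros((H + 1, W + 1), dtype=np.int64)
    sat[1:, 1:] = np.cumsum(np.cumsum(free.astype(np.int64), axis=0), axis=1)
    window = (
        sat[h:, w:] - sat[:-h, w:] - sat[h:, :-w] + sat[:-h, :-w]
    )
    return window == w * h


def propose_paste_location(
    sample_box: Box,
    mask: ForegroundMask,
    existing: Sequence[Box],
    rng: np.random.Generator,
    max_attempts: int = 100,
) -> Optional[Box]:
    """Seeded rejection sampling for a zero-overlap paste location.

    Proposes uniformly random top-left positions and accepts the first whose
    box lies entirely on free foreground (inside the image, zero outer overlap,
    zero overlap with ``existing``).  Returns ``None`` after ``max_attempts``
    rejections.  When no feasible position exists at all, raises
    :class:`InfeasiblePlacementError` instead, so a guaranteed failure is
    distinguishable from an unlucky one.
    """
    if max_attempts < 1:
        raise ValueError("max_attempts must be >= 1")
    w, h = sample_box.width, sample_box.height
    H, W = mask.height, mask.width
    if w > W or h > H:
        raise InfeasiblePlacementError(
            f"sample {w}x{h} does not fit inside image {W}x{H}"
        )
    free = _free_pixels(mask, existing)
    feasible = _feasible_positions(free, w, h)
    if feasible.size == 0 or not feasible.any():
        raise InfeasiblePlacementError(
            f"no {w}x{h} placement satisfies the zero-overlap constraint"
        )
    for _ in range(max_attempts):
        x = int(rng.integers(0, W - w + 1))
        y = int(rng.integers(0, H - h + 1))
        if feasible[y, x]:
            return Box(x, y, x + w, y + h)
    return None


# --------------------------------------------------------------------------
# Copy-paste augmentation
# --------------------------------------------------------------------------

@dataclass
class PasteConfig:
    """Configuration of the copy-paste enhancement.

    ``copies_per_image`` fixes the number of paste attempts; when ``None``,
    targets are pasted until the image holds ``min_targets`` annotations or
    attempts are exhausted.  ``harmonize`` enables automatic brightness
    matching of the pasted patch to its destination neighbourhood (a
    documented, non-equivalent substitute for manual colour retouching;
    off by default).
    """

    copies_per_image: Optional[int] = None
    min_targets: int = 10
    max_attempts: int = 100
    harmonize: bool = False
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.max_attempts < 1:
            raise ValueError("max_attempts must be >= 1")
        if self.copies_per_image is not None and self.copies_per_image < 0:
            raise ValueError("copies_per_image must be >= 0")


@dataclass
class PasteOutcome:
    """Bookkeeping of one augmentation call."""

    attempts: int = 0
    successes: int = 0
    random_failures: int = 0
    infeasible_failures: int = 0


def _harmonize_patch(patch: np.ndarray, image: np.ndarray, dest: Box, margin: int = 4) -> np.ndarray:
    """Match the patch's mean/std intensity to a ring around the destination."""
    y0 = max(0, dest.y0 - margin)
    y1 = min(image.shape[0], dest.y1 + margin)
    x0 = max(0, dest.x0 - margin)
    x1 = min(image.shape[1], dest.x1 + margin)
    ring = image[y0:y1, x0:x1].astype(np.float64)
    p = patch.astype(np.float64)
    p_std = p.std()
    if p_std < 1e-6:
        adjusted = p - p.mean() + ring.mean()
    else:
        adjusted = (p - p.mean()) / p_std * ring.std() + ring.mean()
    return np.clip(adjusted, 0, 255).astype(patch.dtype)


def copy_paste_augment(
    image: np.ndarray,
    annotations: Sequence[Annotation],
    mask: ForegroundMask,
    config: PasteConfig,
    rng: Optional[np.random.Generator] = None,
):
    """Copy existing targets to new zero-overlap foreground locations.

    Returns ``(augmented image, augmented annotations, overlap reports, outcome)``.
    Original pixels outside pasted boxes and all original annotations are
    preserved; each pasted annotation carries ``source=pasted`` and its source
    sample's class.  The sample set grows cumulatively: earlier pastes join the
    overlap constraint for later ones.
    """
    image = np.asarray(image)
    if image.shape[:2] != (mask.height, mask.width):
        raise ValueError("mask does not match image dimensions")
    img_box = Box(0, 0, mask.width, mask.height)
    for a in annotations:
        if not img_box.contains_box(a.box):
            raise ValueError(f"annotation box {a.box} exceeds image bounds")

    if rng is None:
        rng = np.random.default_rng(config.seed)

    out_img = image.copy()
    out_anns = list(annotations)
    reports: list = []
    outcome = PasteOutcome()

    sources = [a for a in annotations if a.source == Source.ORIGINAL] or list(annotations)
    if not sources:
        warnings.warn("no source samples to copy; returning input unchanged")
        return out_img, out_anns, reports, outcome

    if config.copies_per_image is not None:
        n_requested = config.copies_per_image
    else:
        n_requested = max(0, config.min_targets - len(out_anns))

    for _ in range(n_requested):
        src = sources[int(rng.integers(0, len(sources)))]
        existing = [a.box for a in out_anns]
        outcome.attempts += 1
        try:
            dest = propose_paste_location(
                src.box, mask, existing, rng, max_attempts=config.max_attempts
            )
        except InfeasiblePlacementError:
            outcome.infeasible_failures += 1
            continue
        if dest is None:
            outcome.random_failures += 1
            continue
        patch = image[src.box.y0 : src.box.y1, src.box.x0 : src.box.x1]
        if config.harmonize:
            patch = _harmonize_patch(patch, out_img, dest)
        out_img[dest.y0 : dest.y1, dest.x0 : dest.x1] = patch
        reports.append(overlap_report(dest, mask, existing))
        out_anns.append(Annotation(box=dest, class_id=src.class_id, source=Source.PASTED))
        outcome.successes += 1

    if n_requested > 0 and outcome.successes == 0:
        warnings.warn("no valid paste placement found; image returned unchanged")
    return out_img, out_anns, reports, outcome


# --------------------------------------------------------------------------
# Offline resampling
# --------------------------------------------------------------------------

def offline_resample(dataset: DetectionDataset, factor: int) -> DetectionDataset:
    """Duplicate every record ``factor`` times with fresh record identities.

    Duplicates reference the same underlying image and equal annotation lists;
    per-record stochastic preprocessing downstream differentiates them, which
    is what makes the duplication useful rather than a source of overfitting.
    """
    if factor < 1:
        raise ValueError(f"resampling factor must be >= 1, got {factor}")
    records = []
    next_id = 0
    for rec in dataset.records:
        for _ in range(factor):
            records.append(replace(rec, record_id=next_id, annotations=list(rec.annotations)))
            next_id += 1
    return DetectionDataset(records=records, categories=dict(dataset.categories), root=dataset.root)
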