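"""Synthetic small-target detection scenes.

Field imagery of citrus pests is characterised by a textured canopy
foreground on a removable background, very small dark targets (psyllids of a
few pixels, fruit flies roughly twice as large), sparse right-skewed
per-image counts, and unannotated distractors (branches, stems, withered
leaves) that share the targets' colour statistics.  This module renders
scenes with exactly that structure so every other module is testable without
any field data: each scene carries its ground-truth foreground mask and
pixel-tight bounding-box annotations.

What the generator does NOT emulate: real illumination variation, motion
blur, occlusion, and the true appearance of insects — passing tests on these
scenes validate geometry, constraint enforcement, and training mechanics,
not field accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Tuple, Union

import numpy as np
from scipy.ndimage import gaussian_filter

from .boxes import (
    Annotation,
    Box,
    DatasetRecord,
    DetectionDataset,
    DEFAULT_CATEGORIES,
    ForegroundMask,
    Source,
)
from .coco import write_coco

__all__ = ["SceneConfig", "generate_scene", "generate_dataset"]


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of one synthetic scene.

    Per-class target counts may be fixed (``n_psyllids``/``n_flies``) or drawn
    from a right-skewed truncated-geometric distribution (most images hold
    three or fewer targets).  Fly sizes are ~2x psyllid sizes, mirroring the
    2.5 mm vs 5 mm body lengths of the two pests.  ``contrast`` scales how
    much darker targets are than the canopy; distractor blobs share the
    target colour distribution but are never annotated.
    """

    width: int = 512
    height: int = 512
    coverage: float = 0.6
    n_psyllids: Optional[int] = None
    n_flies: Optional[int] = None
    count_geometric_p: float = 0.45  # P(success) of the truncated geometric count draw
    max_count: int = 8
    psyllid_size: Tuple[int, int] = (4, 12)
    fly_size: Tuple[int, int] = (8, 24)
    contrast: float = 0.5
    n_distractors: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.coverage < 1.0:
            raise ValueError("coverage must be in (0, 1)")
        for lo, hi in (self.psyllid_size, self.fly_size):
            if not (0 < lo <= hi):
                raise ValueError("size ranges must be positive and ordered")
        if self.seed is None:
            raise ValueError("a seed is mandatory for reproducible scenes")


def _smooth_noise(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Zero-mean, unit-variance smooth random field.

    Synthesized at a capped working resolution and bilinearly upsampled, so
    cost stays bounded for high-resolution frames (e.g. the 4000x5000
    tiling profile) while small scenes are generated directly.
    """
    from skimage.transform import resize as _sk_resize

    h, w = shape
    cap = 256
    factor = max(1, int(np.ceil(max(h, w) / cap)))
    if factor == 1:
        f = gaussian_filter(rng.standard_normal((h, w)), sigma=sigma, mode="reflect")
    else:
        ch = max(8, -(-h // factor))
        cw = max(8, -(-w // factor))
        coarse = gaussian_filter(
            rng.standard_normal((ch, cw)), sigma=max(sigma / factor, 0.5), mode="reflect"
        )
        f = _sk_resize(coarse, (h, w), order=1, preserve_range=True, anti_aliasing=False)
    f = f.astype(np.float32)
    f -= f.mean()
    s = f.std()
    return f / s if s > 0 else f


def _foreground_mask(rng: np.random.Generator, h: int, w: int, coverage: float) -> np.ndarray:
    """Irregular leaf/trunk-like region covering ~``coverage`` of the frame."""
    fieldmap = _smooth_noise(rng, (h, w), sigma=max(h, w) / 10)
    thresh = np.quantile(fieldmap, 1.0 - coverage)
    return fieldmap >= thresh


def _paint_background(rng: np.random.Generator, h: int, w: int) -> np.ndarray:
    base = np.array([108.0, 96.0, 84.0], dtype=np.float32)  # dull earth tone
    tex = _smooth_noise(rng, (h, w), sigma=6)[..., None] * 18
    img = base[None, None, :] + tex
    img += rng.standard_normal((h, w, 3), dtype=np.float32) * 4
    return img


def _paint_foreground(rng: np.random.Generator, img: np.ndarray, mask: np.ndarray) -> None:
    h, w = mask.shape
    base = np.array([66.0, 150.0, 62.0], dtype=np.float32)  # canopy green
    tex = _smooth_noise(rng, (h, w), sigma=4)[..., None] * 22
    leaf = base[None, None, :] + tex
    leaf += rng.standard_normal((h, w, 3), dtype=np.float32) * 5
    img[mask] = leaf[mask]


def _draw_count(rng: np.random.Generator, cfg: SceneConfig) -> int:
    # right-skewed: geometric(p) - 1, truncated at max_count
    return int(min(rng.geometric(cfg.count_geometric_p) - 1, cfg.max_count))


def _ellipse_pixels(w: int, h: int) -> np.ndarray:
    """Boolean w x h stamp of a filled ellipse touching all four box edges."""
    yy, xx = np.mgrid[0:h, 0:w]
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    a = max(w / 2.0, 0.5)
    b = max(h / 2.0, 0.5)
    stamp = ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0
    # guarantee the stamp touches every edge so the annotation box is tight
    stamp[int(round(cy)), 0] = stamp[int(round(cy)), w - 1] = True
    stamp[0, int(round(cx))] = stamp[h - 1, int(round(cx))] = True
    return stamp


def _free_position(
    rng: np.random.Generator,
    allowed: np.ndarray,
    w: int,
    h: int,
    attempts: int = 200,
) -> Optional[Tuple[int, int]]:
    H, W = allowed.shape
    if w > W or h > H:
        return None
    # cheap seeded rejection sampling first; exact enumeration only as fallback
    for _ in range(attempts):
        x = int(rng.integers(0, W - w + 1))
        y = int(rng.integers(0, H - h + 1))
        if allowed[y : y + h, x : x + w].all():
            return x, y
    sat = np.zeros((H + 1, W + 1), dtype=np.int64)
    sat[1:, 1:] = np.cumsum(np.cumsum(allowed, axis=0, dtype=np.int64), axis=1)
    window = sat[h:, w:] - sat[:-h, w:] - sat[h:, :-w] + sat[:-h, :-w]
    ys, xs = np.nonzero(window == w * h)
    if len(ys) == 0:
        return None
    i = int(rng.integers(0, len(ys)))
    return int(xs[i]), int(ys[i])


def _target_color(rng: np.random.Generator, contrast: float) -> np.ndarray:
    """Dark grey-brown, the shared palette of pests and woody distractors.

    The red channel strictly exceeds green (insect/bark tone) while canopy
    pixels always have green exceeding red, so painted target pixels are
    recoverable from the raster exactly.  Each target is flat-coloured.
    """
    c = (65.0 - 40.0 * contrast) + rng.uniform(-10.0, 10.0)
    return np.clip(np.array([c + 14.0, c, c - 10.0]), 5, 110)


def generate_scene(config: SceneConfig):
    """Render one scene.

    Returns ``(image uint8 HxWx3, ForegroundMask, annotations)``.  Targets are
    dark filled ellipses placed so their whole bounding box lies on foreground
    and boxes never overlap each other or distractors; annotations are tight
    by construction.  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    h, w = config.height, config.width
    if h < 8 or w < 8:
        raise ValueError("scene too small")

    fg = _foreground_mask(rng, h, w, config.coverage)
    img = _paint_background(rng, h, w)
    _paint_foreground(rng, img, fg)

    n_psyllids = config.n_psyllids if config.n_psyllids is not None else _draw_count(rng, config)
    n_flies = config.n_flies if config.n_flies is not None else _draw_count(rng, config)

    # box placements must stay on foreground and off previously placed boxes
    allowed = fg.copy()
    annotations: List[Annotation] = []
    plan = [(0, config.psyllid_size)] * n_psyllids + [(1, config.fly_size)] * n_flies
    for class_id, (lo, hi) in plan:
        bw = int(rng.integers(lo, hi + 1))
        bh = int(rng.integers(lo, hi + 1))
        pos = _free_position(rng, allowed, bw, bh)
        if pos is None:
            raise ValueError(
                f"cannot place a {bw}x{bh} target: foreground too small for the "
                f"requested target count"
            )
        x, y = pos
        stamp = _ellipse_pixels(bw, bh)
        color = _target_color(rng, config.contrast)
        region = img[y : y + bh, x : x + bw]
        region[stamp] = color
        annotations.append(
            Annotation(box=Box(x, y, x + bw, y + bh), class_id=class_id, source=Source.ORIGINAL)
        )
        allowed[y : y + bh, x : x + bw] = False

    # distractors: same palette, no annotation (hard negatives)
    lo, hi = config.psyllid_size
    for _ in range(config.n_distractors):
        bw = int(rng.integers(lo, 2 * hi + 1))
        bh = int(rng.integers(lo, 2 * hi + 1))
        pos = _free_position(rng, allowed, bw, bh)
        if pos is None:
            continue
        x, y = pos
        stamp = _ellipse_pixels(bw, bh)
        color = _target_color(rng, config.contrast * 0.9)
        img[y : y + bh, x : x + bw][stamp] = color
        allowed[y : y + bh, x : x + bw] = False

    image = np.clip(img, 0, 255).astype(np.uint8)
    return image, ForegroundMask(fg), annotations


def generate_dataset(
    config: SceneConfig,
    n_images: int,
    out_dir: Union[str, Path, None] = None,
) -> DetectionDataset:
    """Generate ``n_images`` scenes; optionally write PNGs + masks + COCO JSON.

    Scene ``i`` uses seed ``config.seed + i`` so the dataset is reproducible
    and individual scenes can be regenerated in isolation.  When ``out_dir``
    is given, the on-disk layout is ``images/``, ``masks/`` and
    ``annotations.json``; reloading that JSON yields the same dataset.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    from dataclasses import replace as _replace

    records = []
    for i in range(n_images):
        cfg_i = _replace(config, seed=config.seed + i)
        image, mask, anns = generate_scene(cfg_i)
        records.append(
            DatasetRecord(
                record_id=i,
                image=image,
                width=config.width,
                height=config.height,
                annotations=anns,
                mask=mask,
                file_name=f"images/scene_{i:05d}.png",
                mask_file_name=f"masks/scene_{i:05d}.png",
            )
        )
    dataset = DetectionDataset(records=records, categories=dict(DEFAULT_CATEGORIES))

    if out_dir is not None:
        from PIL import Image

        out = Path(out_dir)
        (out / "images").mkdir(parents=True, exist_ok=True)
        (out / "masks").mkdir(parents=True, exist_ok=True)
        for rec in records:
            Image.fromarray(rec.image).save(out / rec.file_name)
            rec.mask.to_png(out / rec.mask_file_name)
        write_coco(dataset, out / "annotations.json")
        dataset.root = out
    return dataset
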