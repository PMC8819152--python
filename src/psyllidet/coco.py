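"""COCO-dialect JSON annotation I/O.

The on-disk dialect is the standard COCO object-detection layout: top-level
``images``, ``annotations`` (with ``bbox`` as ``[x, y, w, h]``) and
``categories``.  Internal half-open integer boxes convert to/from xywh
losslessly.  Annotation provenance (original vs pasted) rides in a
non-standard ``source`` key that standard tooling ignores.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

from .boxes import (
    Annotation,
    Box,
    DatasetRecord,
    DetectionDataset,
    ForegroundMask,
    Source,
)


class CocoParseError(ValueError):
    """Raised for structurally invalid COCO JSON, naming the offending record."""


def _require(mapping: dict, key: str, ctx: str):
    if key not in mapping:
        raise CocoParseError(f"{ctx}: missing required key {key!r}")
    return mapping[key]


def read_coco(path: Union[str, Path]) -> DetectionDataset:
    """Read a COCO-dialect JSON file into a :class:`DetectionDataset`.

    Image pixel data is not loaded; records keep ``file_name`` paths resolved
    relative to the JSON file's directory.  Masks are attached when a
    ``mask_file_name`` key is present and the file exists.
    """
    path = Path(path)
    with open(path) as fh:
        doc = json.load(fh)
    for key in ("images", "annotations", "categories"):
        _require(doc, key, f"{path.name}")

    categories = {}
    for cat in doc["categories"]:
        cid = _require(cat, "id", "category record")
        categories[int(cid)] = cat.get("name", str(cid))

    records = {}
    for img in doc["images"]:
        iid = int(_require(img, "id", "image record"))
        w = int(_require(img, "width", f"image {iid}"))
        h = int(_require(img, "height", f"image {iid}"))
        if w <= 0 or h <= 0:
            raise CocoParseError(f"image {iid}: non-positive size {w}x{h}")
        fname = img.get("file_name")
        mask = None
        mask_name = img.get("mask_file_name")
        if mask_name is not None and (path.parent / mask_name).exists():
            mask = ForegroundMask.from_png(path.parent / mask_name)
        records[iid] = DatasetRecord(
            record_id=iid,
            image=str(path.parent / fname) if fname else None,
            width=w,
            height=h,
            annotations=[],
            mask=mask,
            file_name=fname,
            mask_file_name=mask_name,
        )

    for ann in doc["annotations"]:
        aid = ann.get("id", "?")
        iid = int(_require(ann, "image_id", f"annotation {aid}"))
        if iid not in records:
            raise CocoParseError(f"annotation {aid}: dangling image_id {iid}")
        x, y, w, h = _require(ann, "bbox", f"annotation {aid}")
        if w <= 0 or h <= 0:
            raise CocoParseError(f"annotation {aid}: non-positive bbox extent ({w}, {h})")
        cid = int(_require(ann, "category_id", f"annotation {aid}"))
        if cid not in categories:
            raise CocoParseError(f"annotation {aid}: unknown category_id {cid}")
        source = Source(ann.get("source", "original"))
        records[iid].annotations.append(
            Annotation(box=Box.from_xywh(x, y, w, h), class_id=cid, source=source)
        )

    return DetectionDataset(
        records=[records[k] for k in sorted(records)],
        categories=categories,
        root=path.parent,
    )


def write_coco(dataset: DetectionDataset, path: Union[str, Path]) -> None:
    """Write a dataset as COCO-dialect JSON (annotations only, no pixels)."""
    path = Path(path)
    images = []
    annotations = []
    ann_id = 1
    for rec in dataset.records:
        entry = {
            "id": rec.record_id,
            "width": rec.width,
            "height": rec.height,
            "file_name": rec.file_name or f"image_{rec.record_id:05d}.png",
        }
        if rec.mask_file_name is not None:
            entry["mask_file_name"] = rec.mask_file_name
        images.append(entry)
        for a in rec.annotations:
            annotations.append(
                {
                    "id": ann_id,
                    "image_id": rec.record_id,
                    "category_id": a.class_id,
                    "bbox": a.box.to_xywh(),
                    "area": a.box.area,
                    "iscrowd": 0,
                    "source": a.source.value,
                }
            )
            ann_id += 1
    doc = {
        "images": images,
        "annotations": annotations,
        "categories": [{"id": cid, "name": name} for cid, name in sorted(dataset.categories.items())],
    }
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
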