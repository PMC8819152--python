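"""Detection evaluation: IoU matching, precision-recall, AP and mAP.

AP for one class is the area under the precision-recall curve,
``AP = ∫₀¹ p(r) dr``, computed here with all-point (continuous)
interpolation of the precision envelope — the closest reading of the
integral form; 11-point sampling is available as an option.  mAP is the
arithmetic mean of per-class APs.  Detections are matched greedily in
descending score order: a detection is a true positive iff its IoU with a
still-unmatched ground truth of the same class reaches the threshold.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .boxes import Box, DetectionDataset, iou

__all__ = [
    "Detection",
    "PRCurve",
    "EvalSummary",
    "match_detections",
    "average_precision",
    "mean_average_precision",
    "evaluate",
    "read_detections_json",
    "write_detections_json",
]


@dataclass(frozen=True)
class Detection:
    """A scored predicted box.  Boxes may be fractional (model output)."""

    image_id: int
    class_id: int
    x0: float
    y0: float
    x1: float
    y1: float
    score: float

    def iou_with(self, other: Box) -> float:
        iw = min(self.x1, other.x1) - max(self.x0, other.x0)
        ih = min(self.y1, other.y1) - max(self.y0, other.y0)
        if iw <= 0 or ih <= 0:
            return 0.0
        inter = iw * ih
        a = (self.x1 - self.x0) * (self.y1 - self.y0)
        return inter / (a + other.area - inter)


def match_detections(
    dets: Sequence[Detection],
    gts: Sequence[Box],
    iou_threshold: float = 0.5,
) -> List[bool]:
    """Greedy TP/FP labelling for one class on one image.

    Detections are processed in descending score order (ties broken by input
    order); each is a TP iff its best IoU against a still-unmatched ground
    truth is >= the threshold, and that ground truth is then consumed.
    Returns labels in the original input order.
    """
    order = sorted(range(len(dets)), key=lambda i: -dets[i].score)
    matched = [False] * len(gts)
    labels = [False] * len(dets)
    for i in order:
        best_j, best_iou = -1, 0.0
        for j, gt in enumerate(gts):
            if matched[j]:
                continue
            v = dets[i].iou_with(gt)
            if v > best_iou:
                best_iou, best_j = v, j
        if best_j >= 0 and best_iou >= iou_threshold:
            matched[best_j] = True
            labels[i] = True
    return labels


@dataclass
class PRCurve:
    """Ranked precision-recall pairs for one class.

    ``precision[k]`` / ``recall[k]`` are the cumulative values after the
    k-th ranked detection; recall is non-decreasing along the ranking.
    """

    scores: np.ndarray
    tp: np.ndarray  # bool, rank order
    n_gt: int

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.tp = np.asarray(self.tp, dtype=bool)

    @property
    def precision(self) -> np.ndarray:
        cum_tp = np.cumsum(self.tp)
        ranks = np.arange(1, len(self.tp) + 1)
        return cum_tp / ranks

    @property
    def recall(self) -> np.ndarray:
        if self.n_gt == 0:
            return np.zeros(len(self.tp))
        return np.cumsum(self.tp) / self.n_gt

    @classmethod
    def from_labels(
        cls, scores: Sequence[float], tp_labels: Sequence[bool], n_gt: int
    ) -> "PRCurve":
        scores = np.asarray(scores, dtype=float)
        tp = np.asarray(tp_labels, dtype=bool)
        order = np.argsort(-scores, kind="stable")
        return cls(scores=scores[order], tp=tp[order], n_gt=n_gt)


class UndefinedAPError(ValueError):
    """AP is undefined when there are no ground-truth instances of a class."""


def average_precision(curve: PRCurve, interpolation: str = "all_point") -> float:
    """Area under the precision envelope over recall in [0, 1].

    ``all_point`` integrates the exact staircase with the precision envelope
    ``p_interp(r) = max_{r' >= r} p(r')``; ``eleven_point`` averages the
    envelope at recalls 0, 0.1, ..., 1.0.  Raises :class:`UndefinedAPError`
    when the curve has zero ground truths — never silently 0.
    """
    if curve.n_gt == 0:
        raise UndefinedAPError("AP undefined: class has no ground-truth instances")
    if len(curve.tp) == 0:
        return 0.0
    recall = curve.recall
    precision = curve.precision
    # precision envelope (non-increasing in recall)
    mrec = np.concatenate([[0.0], recall, [recall[-1]]])
    mpre = np.concatenate([[0.0], precision, [0.0]])
    for i in range(len(mpre) - 2, -1, -1):
        mpre[i] = max(mpre[i], mpre[i + 1])
    if interpolation == "all_point":
        idx = np.where(mrec[1:] != mrec[:-1])[0]
        return float(np.sum((mrec[idx + 1] - mrec[idx]) * mpre[idx + 1]))
    if interpolation == "eleven_point":
        pts = []
        for r in np.linspace(0, 1, 11):
            above = mpre[1:][mrec[1:] >= r]
            pts.append(float(above.max()) if above.size else 0.0)
        return float(np.mean(pts))
    raise ValueError(f"unknown interpolation {interpolation!r}")


def mean_average_precision(per_class_ap: Union[Dict[int, float], Sequence[float]]) -> float:
    """Arithmetic mean of per-class APs; order-invariant; empty input is an error."""
    values = list(per_class_ap.values()) if isinstance(per_class_ap, dict) else list(per_class_ap)
    if not values:
        raise ValueError("mAP requires at least one class with a defined AP")
    return float(np.mean(values))


@dataclass
class EvalSummary:
    """Per-class AP (None where undefined) and their mean."""

    ap_per_class: Dict[int, Optional[float]]
    map: float
    curves: Dict[int, PRCurve] = field(default_factory=dict)

    def to_json(self, path: Union[str, Path]) -> None:
        doc = {
            "ap_per_class": {str(k): v for k, v in self.ap_per_class.items()},
            "mAP": self.map,
            "pr_curves": {
                str(k): {
                    "recall": c.recall.tolist(),
                    "precision": c.precision.tolist(),
                    "scores": c.scores.tolist(),
                    "n_gt": c.n_gt,
                }
                for k, c in self.curves.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)


def evaluate(
    dataset: DetectionDataset,
    detections: Sequence[Detection],
    iou_threshold: float = 0.5,
    interpolation: str = "all_point",
) -> EvalSummary:
    """Per-class PR curves, AP and mAP over a dataset.

    Classes with zero ground truths are excluded from the mAP mean with a
    warning (their AP is undefined, not 0).  Detections referencing an
    unknown category raise an error naming it.
    """
    known = set(dataset.categories)
    for d in detections:
        if d.class_id not in known:
            raise ValueError(f"detection references unknown category id {d.class_id}")

    image_ids = {r.record_id for r in dataset.records}
    for d in detections:
        if d.image_id not in image_ids:
            raise ValueError(f"detection references unknown image id {d.image_id}")

    ap_per_class: Dict[int, Optional[float]] = {}
    curves: Dict[int, PRCurve] = {}
    defined: Dict[int, float] = {}
    for cid in sorted(known):
        scores: List[float] = []
        labels: List[bool] = []
        n_gt = 0
        for rec in dataset.records:
            gts = [a.box for a in rec.annotations if a.class_id == cid]
            n_gt += len(gts)
            dets = [d for d in detections if d.image_id == rec.record_id and d.class_id == cid]
            tp = match_detections(dets, gts, iou_threshold)
            scores.extend(d.score for d in dets)
            labels.extend(tp)
        curve = PRCurve.from_labels(scores, labels, n_gt)
        curves[cid] = curve
        if n_gt == 0:
            warnings.warn(
                f"class {cid} ({dataset.categories[cid]}) has no ground truths; "
                "AP undefined and excluded from mAP"
            )
            ap_per_class[cid] = None
        else:
            ap = average_precision(curve, interpolation)
            ap_per_class[cid] = ap
            defined[cid] = ap

    return EvalSummary(
        ap_per_class=ap_per_class,
        map=mean_average_precision(defined),
        curves=curves,
    )


# --------------------------------------------------------------------------
# COCO detection-results JSON
# --------------------------------------------------------------------------

def write_detections_json(detections: Sequence[Detection], path: Union[str, Path]) -> None:
    """COCO detection-results dialect: a list of image_id/category_id/bbox/score."""
    doc = [
        {
            "image_id": d.image_id,
            "category_id": d.class_id,
            "bbox": [d.x0, d.y0, d.x1 - d.x0, d.y1 - d.y0],
            "score": d.score,
        }
        for d in detections
    ]
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def read_detections_json(path: Union[str, Path]) -> List[Detection]:
    with open(path) as fh:
        doc = json.load(fh)
    out = []
    for rec in doc:
        x, y, w, h = rec["bbox"]
        out.append(
            Detection(
                image_id=int(rec["image_id"]),
                class_id=int(rec["category_id"]),
                x0=float(x),
                y0=float(y),
                x1=float(x) + float(w),
                y1=float(y) + float(h),
                score=float(rec["score"]),
            )
        )
    return out
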