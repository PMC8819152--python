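"""Brute-force reference implementations used to check the library.

Everything here is deliberately naive — per-pixel loops, exhaustive
threshold enumeration, full sorts — and shares no code with the package
paths it verifies.
"""

from __future__ import annotations

from typing import List, Sequence, Tuple

import numpy as np


def pixel_intersection_area(a, b) -> int:
    """Count pixels lying in both half-open boxes by exhaustive looping."""
    count = 0
    for y in range(min(a.y0, b.y0), max(a.y1, b.y1)):
        for x in range(min(a.x0, b.x0), max(a.x1, b.x1)):
            if a.x0 <= x < a.x1 and a.y0 <= y < a.y1 and b.x0 <= x < b.x1 and b.y0 <= y < b.y1:
                count += 1
    return count


def pixel_union_area(a, b) -> int:
    count = 0
    for y in range(min(a.y0, b.y0), max(a.y1, b.y1)):
        for x in range(min(a.x0, b.x0), max(a.x1, b.x1)):
            in_a = a.x0 <= x < a.x1 and a.y0 <= y < a.y1
            in_b = b.x0 <= x < b.x1 and b.y0 <= y < b.y1
            if in_a or in_b:
                count += 1
    return count


def pixel_overlap_rates(copy_box, mask_values: np.ndarray, existing) -> Tuple[float, float]:
    """Outer-region and sample overlap rates by per-pixel counting."""
    h, w = mask_values.shape
    outer_total = 0
    outer_hits = 0
    occupied = np.zeros((h, w), dtype=bool)
    for b in existing:
        for y in range(b.y0, b.y1):
            for x in range(b.x0, b.x1):
                occupied[y, x] = True
    samples_total = sum(b.area for b in existing)
    sample_hits = 0
    for y in range(h):
        for x in range(w):
            inside_copy = copy_box.x0 <= x < copy_box.x1 and copy_box.y0 <= y < copy_box.y1
            if not mask_values[y, x]:
                outer_total += 1
                if inside_copy:
                    outer_hits += 1
            if inside_copy and occupied[y, x]:
                sample_hits += 1
    u_outer = outer_hits / outer_total if outer_total else 0.0
    u_samples = sample_hits / samples_total if samples_total else 0.0
    return u_outer, u_samples


def greedy_match(det_boxes, det_scores, gt_boxes, iou_fn, threshold: float) -> List[bool]:
    """Naive greedy matching in descending score order (stable on ties)."""
    order = sorted(range(len(det_boxes)), key=lambda i: (-det_scores[i], i))
    taken = [False] * len(gt_boxes)
    labels = [False] * len(det_boxes)
    for i in order:
        best, best_iou = -1, 0.0
        for j in range(len(gt_boxes)):
            if taken[j]:
                continue
            v = iou_fn(det_boxes[i], gt_boxes[j])
            if v > best_iou:
                best, best_iou = j, v
        if best >= 0 and best_iou >= threshold:
            taken[best] = True
            labels[i] = True
    return labels


def threshold_enumeration_ap(scores: Sequence[float], tp: Sequence[bool], n_gt: int) -> float:
    """AP by enumerating every score threshold and integrating the staircase.

    At each distinct threshold t, precision and recall are computed over the
    detections with score >= t; the area under the precision envelope is then
    summed over recall increments.
    """
    assert n_gt > 0
    scores = np.asarray(scores, dtype=float)
    tp = np.asarray(tp, dtype=bool)
    thresholds = sorted(set(scores.tolist()), reverse=True)
    points = []  # (recall, precision)
    for t in thresholds:
        sel = scores >= t
        n_det = int(sel.sum())
        n_tp = int(tp[sel].sum())
        points.append((n_tp / n_gt, n_tp / n_det if n_det else 0.0))
    points.sort()
    ap = 0.0
    prev_r = 0.0
    for k, (r, _) in enumerate(points):
        if r == prev_r:
            continue
        p_env = max(p for rr, p in points if rr >= r)
        ap += (r - prev_r) * p_env
        prev_r = r
    return ap


def full_sort_ohem(losses: np.ndarray, positive: np.ndarray, indices: np.ndarray,
                   n_pos: int, n_neg: int) -> Tuple[List, List]:
    """Reference hard-example selection: full sort then prefix, per polarity."""
    pos = [(float(l), int(i)) for l, p, i in zip(losses, positive, indices) if p]
    neg = [(float(l), int(i)) for l, p, i in zip(losses, positive, indices) if not p]
    pos.sort(key=lambda t: (-t[0], t[1]))
    neg.sort(key=lambda t: (-t[0], t[1]))
    return [i for _, i in pos[:n_pos]], [i for _, i in neg[:n_neg]]
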