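"""Cascade two-stage detector over the attention backbone + ASPP + FPN.

Pipeline: the backbone emits four parallel-resolution maps; a sawtooth
pyramid refines each branch independently; top-down fusion aligns them into
a four-level feature pyramid.  A small region-proposal head scores one
square anchor per pyramid cell; proposals feed three cascaded detection
heads, where stage t is supervised at an increasing IoU threshold and
consumes stage t-1's regressed boxes.  Hard-example mining ranks per-ROI
losses within each stage and keeps the top 64 positives / 192 negatives;
stage losses combine 1 : 0.5 : 0.25 into the total training loss.

Everything runs on the NumPy autograd engine; the ``tiny`` profile trains a
smoke-test model on a CPU in minutes.  This implements the method at desk
scale — it is not a pretrained field model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from ..boxes import Annotation, Box
from ..evaluation import Detection
from ..nn import SGD, Linear, Module, Tensor, concat, no_grad
from ..nn.layers import Conv2d
from .aspp import AsppConfig, SawtoothAspp, build_sawtooth_aspp
from .backbone import BackboneConfig, ImprovedBackbone, build_improved_backbone
from .cascade import CascadeConfig, cascade_total_loss
from .fpn import FPN, build_fpn
from .ohem import RoiBatch, ohem_sample

__all__ = ["Detector", "DetectorConfig", "assemble_detector", "build_tiny_detector", "TrainStepLog"]

_LEVEL_STRIDES = (4, 8, 16, 32)
_ANCHOR_SIZES = (8, 16, 32, 64)  # small base scale: targets are tens of pixels
_DELTA_CLAMP = 4.0


# --------------------------------------------------------------------------
# box arithmetic on float arrays (model-internal boxes are fractional)
# --------------------------------------------------------------------------

def _iou_matrix(boxes: np.ndarray, gts: np.ndarray) -> np.ndarray:
    """(N,4) x (M,4) -> (N,M) IoU, boxes as [x0,y0,x1,y1]."""
    if len(boxes) == 0 or len(gts) == 0:
        return np.zeros((len(boxes), len(gts)))
    ix0 = np.maximum(boxes[:, None, 0], gts[None, :, 0])
    iy0 = np.maximum(boxes[:, None, 1], gts[None, :, 1])
    ix1 = np.minimum(boxes[:, None, 2], gts[None, :, 2])
    iy1 = np.minimum(boxes[:, None, 3], gts[None, :, 3])
    iw = np.clip(ix1 - ix0, 0, None)
    ih = np.clip(iy1 - iy0, 0, None)
    inter = iw * ih
    a = (boxes[:, 2] - boxes[:, 0]) * (boxes[:, 3] - boxes[:, 1])
    b = (gts[:, 2] - gts[:, 0]) * (gts[:, 3] - gts[:, 1])
    union = a[:, None] + b[None, :] - inter
    return np.where(union > 0, inter / np.maximum(union, 1e-12), 0.0)


def _encode_deltas(anchors: np.ndarray, gts: np.ndarray) -> np.ndarray:
    aw = anchors[:, 2] - anchors[:, 0]
    ah = anchors[:, 3] - anchors[:, 1]
    ax = anchors[:, 0] + 0.5 * aw
    ay = anchors[:, 1] + 0.5 * ah
    gw = gts[:, 2] - gts[:, 0]
    gh = gts[:, 3] - gts[:, 1]
    gx = gts[:, 0] + 0.5 * gw
    gy = gts[:, 1] + 0.5 * gh
    return np.stack(
        [(gx - ax) / aw, (gy - ay) / ah, np.log(gw / aw), np.log(gh / ah)], axis=1
    )


def _apply_deltas(anchors: np.ndarray, deltas: np.ndarray) -> np.ndarray:
    aw = anchors[:, 2] - anchors[:, 0]
    ah = anchors[:, 3] - anchors[:, 1]
    ax = anchors[:, 0] + 0.5 * aw
    ay = anchors[:, 1] + 0.5 * ah
    d = np.clip(deltas, -_DELTA_CLAMP, _DELTA_CLAMP)
    cx = ax + d[:, 0] * aw
    cy = ay + d[:, 1] * ah
    w = aw * np.exp(d[:, 2])
    h = ah * np.exp(d[:, 3])
    return np.stack([cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2], axis=1)


def _clip_boxes(boxes: np.ndarray, width: int, height: int) -> np.ndarray:
    out = boxes.copy()
    out[:, 0] = np.clip(out[:, 0], 0, width - 1)
    out[:, 1] = np.clip(out[:, 1], 0, height - 1)
    out[:, 2] = np.clip(out[:, 2], 1, width)
    out[:, 3] = np.clip(out[:, 3], 1, height)
    out[:, 2] = np.maximum(out[:, 2], out[:, 0] + 1)
    out[:, 3] = np.maximum(out[:, 3], out[:, 1] + 1)
    return out


def _nms(boxes: np.ndarray, scores: np.ndarray, threshold: float) -> np.ndarray:
    order = np.argsort(-scores, kind="stable")
    keep = []
    while len(order):
        i = order[0]
        keep.append(i)
        if len(order) == 1:
            break
        rest = order[1:]
        ious = _iou_matrix(boxes[rest], boxes[i : i + 1])[:, 0]
        order = rest[ious < threshold]
    return np.asarray(keep, dtype=np.intp)


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DetectorConfig:
    num_classes: int = 2
    fpn_channels: int = 16
    head_hidden: int = 32
    rpn_pre_nms: int = 256
    rpn_post_nms: int = 64
    rpn_nms_threshold: float = 0.7
    rpn_pos_iou: float = 0.4
    rpn_neg_iou: float = 0.2
    rpn_batch_per_polarity: int = 16
    ohem_n_pos: int = 64
    ohem_n_neg: int = 192
    use_ohem: bool = True
    score_threshold: float = 0.05
    nms_threshold: float = 0.5
    max_detections: int = 50


class _RpnHead(Module):
    def __init__(self, channels: int, rng):
        super().__init__()
        self.conv = Conv2d(channels, channels, 3, padding=1, rng=rng)
        self.obj = Conv2d(channels, 1, 1, rng=rng)
        self.reg = Conv2d(channels, 4, 1, rng=rng)

    def forward(self, feat: Tensor) -> Tuple[Tensor, Tensor]:
        h = self.conv(feat).relu()
        return self.obj(h), self.reg(h)


class _RoiHead(Module):
    """Per-stage classification + class-agnostic box regression head."""

    def __init__(self, in_features: int, hidden: int, num_classes: int, rng):
        super().__init__()
        self.fc1 = Linear(in_features, hidden, rng=rng)
        self.fc2 = Linear(hidden, hidden, rng=rng)
        self.cls = Linear(hidden, num_classes + 1, rng=rng)  # + background
        self.reg = Linear(hidden, 4, rng=rng)

    def forward(self, feats: Tensor) -> Tuple[Tensor, Tensor]:
        h = self.fc2(self.fc1(feats).relu()).relu()
        return self.cls(h), self.reg(h)


@dataclass
class TrainStepLog:
    total_loss: float          # weighted cascade loss (the headline training curve)
    rpn_loss: float
    stage_losses: Tuple[float, float, float]
    objective: float           # total_loss + rpn_loss, the optimised quantity
    n_proposals: int
    ohem_selected: Tuple[int, ...] = ()


# --------------------------------------------------------------------------
# detector
# --------------------------------------------------------------------------

class Detector(Module):
    def __init__(
        self,
        backbone: ImprovedBackbone,
        aspp_modules: Sequence[SawtoothAspp],
        fpn: FPN,
        cascade: CascadeConfig,
        config: Optional[DetectorConfig] = None,
        rng: Optional[np.random.Generator] = None,
    ):
        super().__init__()
        if len(aspp_modules) != 4:
            raise ValueError("one pyramid module per backbone branch (4) is required")
        for w, m in zip(backbone.config.widths, aspp_modules):
            if m.config.channels != w:
                raise ValueError(
                    f"pyramid channel width {m.config.channels} does not match "
                    f"backbone branch width {w}"
                )
        rng = rng if rng is not None else np.random.default_rng(0)
        self.backbone = backbone
        self.aspp_modules = list(aspp_modules)
        self.fpn = fpn
        self.cascade = cascade
        self.config = config or DetectorConfig()
        c = self.config
        self.rpn = _RpnHead(fpn.out_channels, rng)
        self.heads = [
            _RoiHead(fpn.out_channels * 4, c.head_hidden, c.num_classes, rng)
            for _ in range(cascade.n_stages)
        ]
        self._rng = rng

    # -- feature pyramid ---------------------------------------------------
    def extract_pyramid(self, image: np.ndarray) -> List[Tensor]:
        x = Tensor(image.astype(np.float64).transpose(2, 0, 1)[None] / 255.0 - 0.5)
        branches = self.backbone(x)
        refined = [aspp(b) for aspp, b in zip(self.aspp_modules, branches)]
        return self.fpn(refined)

    # -- anchors / proposals ----------------------------------------------
    @staticmethod
    def _anchors_for_level(h: int, w: int, stride: int, size: int) -> np.ndarray:
        ys, xs = np.mgrid[0:h, 0:w]
        cx = (xs + 0.5) * stride
        cy = (ys + 0.5) * stride
        half = size / 2.0
        return np.stack(
            [cx - half, cy - half, cx + half, cy + half], axis=-1
        ).reshape(-1, 4)

    def _rpn_forward(self, pyramid: Sequence[Tensor]):
        all_anchors, all_obj, all_reg = [], [], []
        for feat, stride, size in zip(pyramid, _LEVEL_STRIDES, _ANCHOR_SIZES):
            obj, reg = self.rpn(feat)
            _, _, fh, fw = feat.shape
            all_anchors.append(self._anchors_for_level(fh, fw, stride, size))
            all_obj.append(obj.reshape(fh * fw))
            all_reg.append(reg.reshape(4, fh * fw).transpose((1, 0)))
        anchors = np.concatenate(all_anchors, axis=0)
        return anchors, concat(all_obj, axis=0), concat(all_reg, axis=0)

    def _proposals(
        self,
        anchors: np.ndarray,
        obj_logits: np.ndarray,
        reg: np.ndarray,
        width: int,
        height: int,
    ) -> np.ndarray:
        c = self.config
        boxes = _clip_boxes(_apply_deltas(anchors, reg), width, height)
        order = np.argsort(-obj_logits, kind="stable")[: c.rpn_pre_nms]
        keep = _nms(boxes[order], obj_logits[order], c.rpn_nms_threshold)
        return boxes[order][keep][: c.rpn_post_nms]

    # -- ROI pooling -------------------------------------------------------
    @staticmethod
    def _roi_level(box: np.ndarray) -> int:
        size = np.sqrt(max((box[2] - box[0]) * (box[3] - box[1]), 1.0))
        return int(np.clip(np.floor(np.log2(size / 8.0 + 1e-9)), 0, 3))

    def _roi_features(self, pyramid: Sequence[Tensor], boxes: np.ndarray) -> Tensor:
        """2x2 adaptive average pooling of each ROI on its assigned level;
        output (N_roi, 4 * fpn_channels)."""
        feats = []
        for box in boxes:
            lvl = self._roi_level(box)
            feat = pyramid[lvl]
            stride = _LEVEL_STRIDES[lvl]
            _, cch, fh, fw = feat.shape
            x0 = int(np.clip(np.floor(box[0] / stride), 0, fw - 1))
            y0 = int(np.clip(np.floor(box[1] / stride), 0, fh - 1))
            x1 = int(np.clip(np.ceil(box[2] / stride), x0 + 1, fw))
            y1 = int(np.clip(np.ceil(box[3] / stride), y0 + 1, fh))
            xm = max(x0 + 1, (x0 + x1) // 2)
            ym = max(y0 + 1, (y0 + y1) // 2)
            xm = min(xm, x1)
            ym = min(ym, y1)
            cells = [
                (y0, ym, x0, xm),
                (y0, ym, xm, x1) if xm < x1 else (y0, ym, x0, xm),
                (ym, y1, x0, xm) if ym < y1 else (y0, ym, x0, xm),
                (ym, y1, xm, x1) if (ym < y1 and xm < x1) else (y0, ym, x0, xm),
            ]
            pooled = [
                feat.crop2d(cy0, cy1, cx0, cx1).mean(axis=(2, 3)).reshape(cch)
                for cy0, cy1, cx0, cx1 in cells
            ]
            feats.append(concat(pooled, axis=0).reshape(1, 4 * cch))
        return concat(feats, axis=0)

    # -- training ----------------------------------------------------------
    def _assign(
        self, proposals: np.ndarray, gt_boxes: np.ndarray, gt_classes: np.ndarray, thr: float
    ):
        """Labels (background = num_classes), matched GT index per proposal."""
        K = self.config.num_classes
        labels = np.full(len(proposals), K, dtype=np.intp)
        matched = np.full(len(proposals), -1, dtype=np.intp)
        if len(gt_boxes):
            ious = _iou_matrix(proposals, gt_boxes)
            best = ious.argmax(axis=1)
            best_iou = ious.max(axis=1)
            pos = best_iou >= thr
            labels[pos] = gt_classes[best[pos]]
            matched[pos] = best[pos]
        return labels, matched

    def _rpn_loss(
        self,
        anchors: np.ndarray,
        obj_logits: Tensor,
        reg: Tensor,
        gt_boxes: np.ndarray,
        rng: np.random.Generator,
    ) -> Tensor:
        c = self.config
        n = len(anchors)
        if len(gt_boxes) == 0:
            neg = rng.choice(n, size=min(2 * c.rpn_batch_per_polarity, n), replace=False)
            return obj_logits.take(neg).bce_with_logits(np.zeros(len(neg))).mean()
        ious = _iou_matrix(anchors, gt_boxes)
        best_iou = ious.max(axis=1)
        best_gt = ious.argmax(axis=1)
        pos_mask = best_iou >= c.rpn_pos_iou
        # force the best anchor for each GT positive so tiny targets are never unmatched
        pos_mask[ious.argmax(axis=0)] = True
        neg_mask = (best_iou < c.rpn_neg_iou) & ~pos_mask
        pos_idx = np.flatnonzero(pos_mask)
        neg_idx = np.flatnonzero(neg_mask)
        if len(pos_idx) > c.rpn_batch_per_polarity:
            pos_idx = rng.choice(pos_idx, size=c.rpn_batch_per_polarity, replace=False)
        n_neg = min(len(neg_idx), max(c.rpn_batch_per_polarity, 2 * len(pos_idx)))
        if len(neg_idx) > n_neg:
            neg_idx = rng.choice(neg_idx, size=n_neg, replace=False)
        sel = np.concatenate([pos_idx, neg_idx])
        targets = np.concatenate([np.ones(len(pos_idx)), np.zeros(len(neg_idx))])
        cls_loss = obj_logits.take(sel).bce_with_logits(targets).mean()
        if len(pos_idx):
            tgt_deltas = _encode_deltas(anchors[pos_idx], gt_boxes[best_gt[pos_idx]])
            reg_loss = reg.take(pos_idx).smooth_l1(tgt_deltas, beta=1.0 / 9.0).mean()
            return cls_loss + reg_loss
        return cls_loss

    def _stage_loss(
        self,
        pyramid: Sequence[Tensor],
        proposals: np.ndarray,
        gt_boxes: np.ndarray,
        gt_classes: np.ndarray,
        stage: int,
    ):
        """One cascade stage: returns (loss tensor, refined boxes, n_selected)."""
        c = self.config
        thr = self.cascade.stage_iou_thresholds[stage]
        labels, matched = self._assign(proposals, gt_boxes, gt_classes, thr)
        feats = self._roi_features(pyramid, proposals)
        cls_logits, reg = self.heads[stage](feats)

        cls_losses = cls_logits.softmax_cross_entropy(labels)  # (N,)
        pos_mask = labels < c.num_classes
        pos_idx = np.flatnonzero(pos_mask)

        reg_losses_np = np.zeros(len(proposals))
        reg_loss_tensor = None
        if len(pos_idx):
            tgt = _encode_deltas(proposals[pos_idx], gt_boxes[matched[pos_idx]])
            per_pos = reg.take(pos_idx).smooth_l1(tgt, beta=1.0 / 9.0).mean(axis=1)
            reg_losses_np[pos_idx] = per_pos.data
            reg_loss_tensor = per_pos

        # rank ROIs: positives by cls + reg, negatives by cls alone
        rank_losses = cls_losses.data + reg_losses_np
        batch = RoiBatch(
            losses=rank_losses, positive=pos_mask, indices=np.arange(len(proposals))
        )
        self.last_roi_batches.append(batch)
        if c.use_ohem:
            sel_pos, sel_neg = ohem_sample(batch, c.ohem_n_pos, c.ohem_n_neg)
            selected = np.concatenate([sel_pos, sel_neg])
        else:
            selected = np.arange(len(proposals))
        self.last_selected_rois.append(np.sort(selected))

        loss = cls_losses.take(selected).mean()
        if reg_loss_tensor is not None:
            sel_pos_set = (
                np.intersect1d(selected, pos_idx) if c.use_ohem else pos_idx
            )
            if len(sel_pos_set):
                keep = np.searchsorted(pos_idx, sel_pos_set)
                loss = loss + reg_loss_tensor.take(keep).mean()

        refined = _apply_deltas(proposals, reg.data)
        return loss, refined, len(selected)

    def compute_losses(self, image: np.ndarray, annotations: Sequence[Annotation],
                       rng: Optional[np.random.Generator] = None):
        """Forward pass with losses for one image.

        Returns ``(objective tensor, TrainStepLog)`` where the objective is the
        weighted cascade loss plus the proposal-head loss.
        """
        rng = rng if rng is not None else self._rng
        h, w = image.shape[:2]
        gt_boxes = np.array(
            [[a.box.x0, a.box.y0, a.box.x1, a.box.y1] for a in annotations], dtype=float
        ).reshape(-1, 4)
        gt_classes = np.array([a.class_id for a in annotations], dtype=np.intp)

        self.last_roi_batches: List[RoiBatch] = []   # per-stage, for audits
        self.last_selected_rois: List[np.ndarray] = []

        pyramid = self.extract_pyramid(image)
        anchors, obj_logits, reg = self._rpn_forward(pyramid)
        rpn_loss = self._rpn_loss(anchors, obj_logits, reg, gt_boxes, rng)

        proposals = self._proposals(anchors, obj_logits.data, reg.data, w, h)
        if len(gt_boxes):
            # guarantee positives at every stage, standard cascade practice
            proposals = np.concatenate([proposals, gt_boxes], axis=0)
        proposals = _clip_boxes(proposals, w, h)

        stage_losses = []
        n_sel = []
        boxes = proposals
        for stage in range(self.cascade.n_stages):
            loss, boxes, n = self._stage_loss(pyramid, boxes, gt_boxes, gt_classes, stage)
            boxes = _clip_boxes(boxes, w, h)
            stage_losses.append(loss)
            n_sel.append(n)

        total = cascade_total_loss(stage_losses, self.cascade.stage_loss_weights)
        objective = total + rpn_loss
        log = TrainStepLog(
            total_loss=float(total.data),
            rpn_loss=float(rpn_loss.data),
            stage_losses=tuple(float(l.data) for l in stage_losses),
            objective=float(objective.data),
            n_proposals=len(proposals),
            ohem_selected=tuple(n_sel),
        )
        return objective, log

    def train_step(self, image: np.ndarray, annotations: Sequence[Annotation],
                   optimizer: SGD, rng: Optional[np.random.Generator] = None) -> TrainStepLog:
        objective, log = self.compute_losses(image, annotations, rng)
        optimizer.zero_grad()
        objective.backward()
        optimizer.step()
        return log

    # -- inference ---------------------------------------------------------
    def detect(self, image: np.ndarray, image_id: int = 0) -> List[Detection]:
        """Scored, class-labelled boxes for one image (boxes clipped to bounds)."""
        c = self.config
        h, w = image.shape[:2]
        with no_grad():
            pyramid = self.extract_pyramid(image)
            anchors, obj_logits, reg = self._rpn_forward(pyramid)
            boxes = self._proposals(anchors, obj_logits.data, reg.data, w, h)
            if len(boxes) == 0:
                return []
            stage_probs = []
            for stage in range(self.cascade.n_stages):
                feats = self._roi_features(pyramid, boxes)
                cls_logits, deltas = self.heads[stage](feats)
                z = cls_logits.data - cls_logits.data.max(axis=1, keepdims=True)
                ez = np.exp(z)
                stage_probs.append(ez / ez.sum(axis=1, keepdims=True))
                boxes = _clip_boxes(_apply_deltas(boxes, deltas.data), w, h)
            probs = np.mean(stage_probs, axis=0)  # average stage scores

        detections: List[Detection] = []
        for cid in range(c.num_classes):
            scores = probs[:, cid]
            keep = scores >= c.score_threshold
            if not keep.any():
                continue
            kb, ks = boxes[keep], scores[keep]
            sel = _nms(kb, ks, c.nms_threshold)
            for i in sel:
                detections.append(
                    Detection(
                        image_id=image_id,
                        class_id=cid,
                        x0=float(kb[i, 0]),
                        y0=float(kb[i, 1]),
                        x1=float(kb[i, 2]),
                        y1=float(kb[i, 3]),
                        score=float(ks[i]),
                    )
                )
        detections.sort(key=lambda d: -d.score)
        return detections[: c.max_detections]


def assemble_detector(
    backbone: ImprovedBackbone,
    aspp_modules: Sequence[SawtoothAspp],
    fpn: FPN,
    cascade: CascadeConfig,
    config: Optional[DetectorConfig] = None,
    rng: Optional[np.random.Generator] = None,
) -> Detector:
    """Wire backbone, per-branch pyramids, fusion and cascade heads into an
    end-to-end trainable detector; inconsistent component shapes fail here."""
    return Detector(backbone, aspp_modules, fpn, cascade, config=config, rng=rng)


def build_tiny_detector(
    seed: int = 0,
    use_attention: bool = True,
    use_ohem: bool = True,
    num_classes: int = 2,
) -> Detector:
    """Test-scale detector: narrow widths, identical structure."""
    rng = np.random.default_rng(seed)
    bcfg = BackboneConfig.make_tiny(use_attention=use_attention)
    backbone = build_improved_backbone(bcfg, rng=rng)
    aspps = [
        build_sawtooth_aspp(AsppConfig(channels=wd), rng=rng) for wd in bcfg.widths
    ]
    fpn = build_fpn(bcfg.widths, out_channels=16, rng=rng)
    det_cfg = DetectorConfig(num_classes=num_classes, use_ohem=use_ohem)
    return assemble_detector(backbone, aspps, fpn, CascadeConfig(), config=det_cfg, rng=rng)
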