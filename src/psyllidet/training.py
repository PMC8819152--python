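"""Smoke-scale training loop for the tiny detector.

Trains on small synthetic scenes, one image per SGD step, cycling through the
dataset.  The headline curve is the weighted cascade total loss; the
optimised objective additionally includes the proposal-head loss.  Start/end
comparisons use window means (first vs last tenth of the iterations, at
least five each) because single-iteration losses fluctuate with the image
drawn at that step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Union

import numpy as np

from .model import Detector, build_tiny_detector
from .nn import SGD
from .synthetic import SceneConfig, generate_dataset

__all__ = ["SmokeTrainResult", "smoke_train", "save_checkpoint", "load_checkpoint"]


@dataclass
class SmokeTrainResult:
    total_losses: List[float]
    rpn_losses: List[float]
    objective_losses: List[float]
    detector: Detector

    @property
    def _window(self) -> int:
        return max(5, len(self.total_losses) // 10)

    @property
    def start_loss(self) -> float:
        return float(np.mean(self.total_losses[: self._window]))

    @property
    def end_loss(self) -> float:
        return float(np.mean(self.total_losses[-self._window :]))


def smoke_train(
    n_images: int = 16,
    iterations: int = 200,
    seed: int = 0,
    image_size: int = 64,
    lr: float = 0.02,
    detector: Optional[Detector] = None,
) -> SmokeTrainResult:
    """Train a tiny detector for ``iterations`` single-image SGD steps.

    Scenes are 64x64 with 1-3 targets each — small enough that one CPU
    finishes 200 iterations in a few minutes while exercising the full
    pipeline (backbone, pyramids, fusion, proposals, three cascade stages,
    hard-example mining).
    """
    rng = np.random.default_rng(seed)
    cfg = SceneConfig(
        width=image_size,
        height=image_size,
        coverage=0.7,
        n_psyllids=2,
        n_flies=1,
        psyllid_size=(5, 10),
        fly_size=(10, 18),
        n_distractors=2,
        seed=seed,
    )
    dataset = generate_dataset(cfg, n_images)

    det = detector if detector is not None else build_tiny_detector(seed=seed)
    opt = SGD(det.parameters(), lr=lr, momentum=0.9, clip=5.0)

    total_losses, rpn_losses, objectives = [], [], []
    for it in range(iterations):
        rec = dataset.records[it % n_images]
        log = det.train_step(rec.image, rec.annotations, opt, rng)
        total_losses.append(log.total_loss)
        rpn_losses.append(log.rpn_loss)
        objectives.append(log.objective)
    return SmokeTrainResult(
        total_losses=total_losses,
        rpn_losses=rpn_losses,
        objective_losses=objectives,
        detector=det,
    )


def save_checkpoint(detector: Detector, path: Union[str, Path]) -> None:
    """Checkpoints are plain ``.npz`` archives of the parameter arrays."""
    np.savez(path, **detector.state_dict())


def load_checkpoint(detector: Detector, path: Union[str, Path]) -> None:
    with np.load(path) as archive:
        detector.load_state_dict({k: archive[k] for k in archive.files})
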