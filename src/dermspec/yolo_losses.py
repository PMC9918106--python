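"""Reference bounding-box, confidence and classification loss terms.

Pure numeric functions over explicit cell assignments: no network, no
gradients.  The box term sums 1 - GIoU over object cells; the confidence
and classification terms are binary cross-entropies with an epsilon clamp
on log arguments (the expressions are undefined at probabilities 0 and 1).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .detection_eval import giou
from .errors import DermspecError

__all__ = [
    "CellAssignment",
    "LossConfig",
    "giou_loss",
    "confidence_loss",
    "classification_loss",
    "load_assignments",
]


@dataclass(frozen=True)
class LossConfig:
    lambda_noobj: float = 0.5
    epsilon: float = 1e-7

    def __post_init__(self) -> None:
        if self.lambda_noobj < 0:
            raise DermspecError("lambda_noobj must be >= 0")
        if not 0 < self.epsilon < 1e-3:
            raise DermspecError("epsilon must lie in (0, 1e-3)")


@dataclass(frozen=True)
class CellAssignment:
    """One (grid cell, box slot) of the detection head."""

    grid_index: int
    box_index: int
    has_object: int
    predicted_box: tuple[float, float, float, float]
    target_box: tuple[float, float, float, float]
    predicted_confidence: float
    target_confidence: float
    predicted_class_probs: tuple[float, ...] = field(default=())
    target_class_probs: tuple[float, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.has_object not in (0, 1):
            raise DermspecError("has_object must be 0 or 1")
        for name in ("predicted_confidence", "target_confidence"):
            if not 0 <= getattr(self, name) <= 1:
                raise DermspecError(f"{name} outside [0, 1]")
        for name in ("predicted_class_probs", "target_class_probs"):
            probs = tuple(float(p) for p in getattr(self, name))
            if any(not 0 <= p <= 1 for p in probs):
                raise DermspecError(f"{name} outside [0, 1]")
            object.__setattr__(self, name, probs)


def _bce(target: np.ndarray, predicted: np.ndarray, epsilon: float) -> np.ndarray:
    p = np.clip(predicted, epsilon, 1 - epsilon)
    return -(target * np.log(p) + (1 - target) * np.log(1 - p))


def giou_loss(assignments: list[CellAssignment]) -> float:
    """Sum of (1 - GIoU) over object cells."""
    return float(
        sum(1 - giou(a.predicted_box, a.target_box) for a in assignments if a.has_object)
    )


def confidence_loss(assignments: list[CellAssignment], config: LossConfig = LossConfig()) -> float:
    """Object-cell BCE plus lambda_noobj-weighted no-object-cell BCE."""
    total = 0.0
    for a in assignments:
        term = float(_bce(
            np.float64(a.target_confidence),
            np.float64(a.predicted_confidence),
            config.epsilon,
        ))
        total += term if a.has_object else config.lambda_noobj * term
    return total


def classification_loss(assignments: list[CellAssignment], config: LossConfig = LossConfig()) -> float:
    """Per-class BCE summed over object cells."""
    total = 0.0
    for a in assignments:
        if not a.has_object:
            continue
        if len(a.predicted_class_probs) != len(a.target_class_probs):
            raise DermspecError("class probability vectors differ in length")
        total += float(
            _bce(
                np.asarray(a.target_class_probs),
                np.asarray(a.predicted_class_probs),
                config.epsilon,
            ).sum()
        )
    return total


def load_assignments(path: str | Path) -> tuple[list[CellAssignment], LossConfig]:
    """Read a JSON fixture: {"lambda_noobj": ..., "epsilon": ...,
    "assignments": [{...CellAssignment fields...}]}."""
    payload = json.loads(Path(path).read_text())
    config = LossConfig(
        lambda_noobj=payload.get("lambda_noobj", 0.5),
        epsilon=payload.get("epsilon", 1e-7),
    )
    assignments = [
        CellAssignment(
            grid_index=rec["grid_index"],
            box_index=rec["box_index"],
            has_object=rec["has_object"],
            predicted_box=tuple(rec["predicted_box"]),
            target_box=tuple(rec["target_box"]),
            predicted_confidence=rec["predicted_confidence"],
            target_confidence=rec["target_confidence"],
            predicted_class_probs=tuple(rec.get("predicted_class_probs", ())),
            target_class_probs=tuple(rec.get("target_class_probs", ())),
        )
        for rec in payload["assignments"]
    ]
    return assignments, config
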