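"""Detection evaluation: IoU/GIoU, greedy matching into an extended
confusion matrix with background false-positive column and background
false-negative row, and the five summary metrics.

Matrix orientation: rows = predicted class (last row = predicted
background, i.e. missed ground truths), columns = true class (last
column = true background, i.e. spurious detections).  The
background-background cell is undefined for detection and fixed at 0.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DermspecError, InvalidBoxError

__all__ = [
    "Detection",
    "GroundTruth",
    "ExtendedConfusionMatrix",
    "ClassMetrics",
    "MetricsTable",
    "iou",
    "giou",
    "match_and_count",
    "class_metrics",
    "f1_from_pr",
    "read_detections_csv",
    "write_detections_csv",
    "read_ground_truth_csv",
    "write_ground_truth_csv",
]

BoxT = tuple[float, float, float, float]  # xmin, ymin, xmax, ymax


def _check_box(box: BoxT) -> BoxT:
    xmin, ymin, xmax, ymax = (float(v) for v in box)
    if not (xmin < xmax and ymin < ymax):
        raise InvalidBoxError(f"degenerate box {box}")
    return xmin, ymin, xmax, ymax


@dataclass(frozen=True)
class Detection:
    image_id: str
    class_index: int
    confidence: float
    box: BoxT

    def __post_init__(self) -> None:
        if not 0 <= self.confidence <= 1:
            raise DermspecError(f"confidence {self.confidence} outside [0, 1]")
        object.__setattr__(self, "box", _check_box(self.box))


@dataclass(frozen=True)
class GroundTruth:
    image_id: str
    class_index: int
    box: BoxT

    def __post_init__(self) -> None:
        object.__setattr__(self, "box", _check_box(self.box))


def _area(box: BoxT) -> float:
    return (box[2] - box[0]) * (box[3] - box[1])


def iou(a: BoxT, b: BoxT) -> float:
    """Intersection over union; 0 for disjoint boxes."""
    a, b = _check_box(a), _check_box(b)
    iw = min(a[2], b[2]) - max(a[0], b[0])
    ih = min(a[3], b[3]) - max(a[1], b[1])
    inter = max(iw, 0.0) * max(ih, 0.0)
    union = _area(a) + _area(b) - inter
    return inter / union


def giou(a: BoxT, b: BoxT) -> float:
    """Generalized IoU: IoU minus the enclosing-box penalty; in (-1, 1]."""
    a, b = _check_box(a), _check_box(b)
    iw = min(a[2], b[2]) - max(a[0], b[0])
    ih = min(a[3], b[3]) - max(a[1], b[1])
    inter = max(iw, 0.0) * max(ih, 0.0)
    union = _area(a) + _area(b) - inter
    enclosing = (max(a[2], b[2]) - min(a[0], b[0])) * (max(a[3], b[3]) - min(a[1], b[1]))
    return inter / union - (enclosing - union) / enclosing


@dataclass
class ExtendedConfusionMatrix:
    """(K+1) x (K+1) counts; see module docstring for orientation."""

    counts: np.ndarray
    class_labels: list[str]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        k = len(self.class_labels)
        if counts.shape != (k + 1, k + 1):
            raise DermspecError(f"counts must be {(k + 1, k + 1)}, got {counts.shape}")
        if counts.min() < 0:
            raise DermspecError("counts must be non-negative")
        if counts[k, k] != 0:
            raise DermspecError("background-background cell must be 0")
        self.counts = counts

    @property
    def n_classes(self) -> int:
        return len(self.class_labels)

    @property
    def correct_count(self) -> int:
        """Trace over the lesion classes."""
        k = self.n_classes
        return int(np.trace(self.counts[:k, :k]))

    def true_class_totals(self) -> np.ndarray:
        """Ground-truth box count per class (column sums incl. background row)."""
        return self.counts[:, : self.n_classes].sum(axis=0)

    def predicted_class_totals(self) -> np.ndarray:
        """Retained detection count per class (row sums incl. background column)."""
        return self.counts[: self.n_classes, :].sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        labels = list(self.class_labels)
        return pd.DataFrame(
            self.counts,
            index=labels + ["Background FN"],
            columns=labels + ["Background FP"],
        )

    def to_text(self) -> str:
        frame = self.to_frame()
        frame.index.name = "Predicted \\ True"
        return frame.to_string()


def match_and_count(
    detections: list[Detection],
    ground_truths: list[GroundTruth],
    class_labels: list[str],
    iou_threshold: float = 0.45,
    confidence_threshold: float = 0.25,
) -> ExtendedConfusionMatrix:
    """Greedy per-image matching into the extended confusion matrix.

    Detections below the confidence threshold are discarded.  Remaining
    detections are processed in descending confidence; each takes the
    unmatched ground truth with the highest IoU >= threshold (ties to the
    earlier ground-truth index).  Unmatched detections land in the
    background column, unmatched ground truths in the background row.
    """
    if not (0 < iou_threshold < 1 and 0 < confidence_threshold < 1):
        raise DermspecError("thresholds must lie in (0, 1)")
    k = len(class_labels)
    for det in detections:
        if not 0 <= det.class_index < k:
            raise DermspecError(f"detection class {det.class_index} out of range")
    for gt in ground_truths:
        if not 0 <= gt.class_index < k:
            raise DermspecError(f"ground-truth class {gt.class_index} out of range")

    counts = np.zeros((k + 1, k + 1), dtype=int)
    gts_by_image: dict[str, list[GroundTruth]] = defaultdict(list)
    dets_by_image: dict[str, list[Detection]] = defaultdict(list)
    for gt in ground_truths:
        gts_by_image[gt.image_id].append(gt)
    for det in detections:
        if det.confidence >= confidence_threshold:
            dets_by_image[det.image_id].append(det)

    for image_id in sorted(set(gts_by_image) | set(dets_by_image)):
        gts = gts_by_image.get(image_id, [])
        dets = sorted(
            dets_by_image.get(image_id, []), key=lambda d: -d.confidence
        )
        gt_boxes = np.array([gt.box for gt in gts], dtype=float).reshape(-1, 4)
        gt_areas = (gt_boxes[:, 2] - gt_boxes[:, 0]) * (gt_boxes[:, 3] - gt_boxes[:, 1])
        matched = np.zeros(len(gts), dtype=bool)
        for det in dets:
            best_j = -1
            if len(gts):
                dx0, dy0, dx1, dy1 = det.box
                iw = np.minimum(gt_boxes[:, 2], dx1) - np.maximum(gt_boxes[:, 0], dx0)
                ih = np.minimum(gt_boxes[:, 3], dy1) - np.maximum(gt_boxes[:, 1], dy0)
                inter = np.clip(iw, 0, None) * np.clip(ih, 0, None)
                union = gt_areas + (dx1 - dx0) * (dy1 - dy0) - inter
                ious = np.where(matched, -1.0, inter / union)
                # argmax returns the first maximum: earlier-index tie-break
                j = int(np.argmax(ious))
                if ious[j] >= iou_threshold:
                    best_j = j
            if best_j >= 0:
                matched[best_j] = True
                counts[det.class_index, gts[best_j].class_index] += 1
            else:
                counts[det.class_index, k] += 1
        for j, gt in enumerate(gts):
            if not matched[j]:
                counts[k, gt.class_index] += 1
    return ExtendedConfusionMatrix(counts, list(class_labels))


UNDEFINED = float("nan")


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else UNDEFINED


@dataclass(frozen=True)
class ClassMetrics:
    precision: float
    recall: float
    specificity: float
    f1: float


@dataclass
class MetricsTable:
    per_class: dict[str, ClassMetrics]
    pooled: ClassMetrics
    accuracy: float
    correct_count: int
    convention: str = "exclude-background"

    def to_frame(self) -> pd.DataFrame:
        rows = {"All": self.pooled.__dict__ | {"accuracy": self.accuracy}}
        for label, cm in self.per_class.items():
            rows[label] = cm.__dict__
        return pd.DataFrame.from_dict(rows, orient="index")


def f1_from_pr(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; undefined (NaN) at P+R=0."""
    if not (0 <= precision <= 1 and 0 <= recall <= 1):
        raise DermspecError("precision and recall must lie in [0, 1]")
    if precision + recall == 0:
        return UNDEFINED
    return 2 * precision * recall / (precision + recall)


def class_metrics(
    matrix: ExtendedConfusionMatrix, precision_convention: str = "exclude-background"
) -> MetricsTable:
    """Per-class and macro-pooled precision/recall/specificity/F1 plus
    accuracy over true-lesion columns.

    ``precision_convention`` controls whether the background-FP cell of a
    predicted-class row enters that class's false positives
    (``include-background``) or not (``exclude-background``, default).
    Zero-denominator metrics are NaN, never silently 0.
    """
    if precision_convention not in ("exclude-background", "include-background"):
        raise DermspecError(f"unknown precision convention {precision_convention!r}")
    k = matrix.n_classes
    counts = matrix.counts.astype(float)
    total = counts.sum()
    per_class: dict[str, ClassMetrics] = {}
    for c, label in enumerate(matrix.class_labels):
        tp = counts[c, c]
        fp = counts[c, :k].sum() - tp
        if precision_convention == "include-background":
            fp += counts[c, k]
        fn = counts[:, c].sum() - tp
        tn = total - tp - fp - fn
        precision = _safe_div(tp, tp + fp)
        recall = _safe_div(tp, tp + fn)
        specificity = _safe_div(tn, tn + fp)
        f1 = (
            f1_from_pr(precision, recall)
            if not (math.isnan(precision) or math.isnan(recall))
            else UNDEFINED
        )
        per_class[label] = ClassMetrics(precision, recall, specificity, f1)

    def _macro(attr: str) -> float:
        values = [getattr(m, attr) for m in per_class.values()]
        finite = [v for v in values if not math.isnan(v)]
        return sum(finite) / len(finite) if finite else UNDEFINED

    pooled = ClassMetrics(*(_macro(a) for a in ("precision", "recall", "specificity", "f1")))
    accuracy = _safe_div(matrix.correct_count, counts[:, :k].sum())
    return MetricsTable(
        per_class, pooled, accuracy, matrix.correct_count, precision_convention
    )


# --- I/O -----------------------------------------------------------------

_DET_COLUMNS = ["image_id", "class_index", "confidence", "xmin", "ymin", "xmax", "ymax"]


def write_detections_csv(detections: list[Detection], path: str | Path) -> None:
    pd.DataFrame(
        [[d.image_id, d.class_index, d.confidence, *d.box] for d in detections],
        columns=_DET_COLUMNS,
    ).to_csv(path, index=False)


def read_detections_csv(path: str | Path) -> list[Detection]:
    frame = pd.read_csv(path)
    return [
        Detection(
            str(r.image_id), int(r.class_index), float(r.confidence),
            (r.xmin, r.ymin, r.xmax, r.ymax),
        )
        for r in frame.itertuples()
    ]


def write_ground_truth_csv(ground_truths: list[GroundTruth], path: str | Path) -> None:
    pd.DataFrame(
        [[g.image_id, g.class_index, *g.box] for g in ground_truths],
        columns=[c for c in _DET_COLUMNS if c != "confidence"],
    ).to_csv(path, index=False)


def read_ground_truth_csv(path: str | Path) -> list[GroundTruth]:
    frame = pd.read_csv(path)
    return [
        GroundTruth(str(r.image_id), int(r.class_index), (r.xmin, r.ymin, r.xmax, r.ymax))
        for r in frame.itertuples()
    ]
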