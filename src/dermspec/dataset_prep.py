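"""Dataset preparation: canvas resize, Pascal-VOC XML <-> YOLO txt label
conversion, and a stratified train/test split.

Internal box convention: 0-based half-open pixel intervals
[xmin, xmax) x [ymin, ymax).  VOC XML files use the common 1-based
inclusive dialect; the reader/writer convert at the boundary.
"""

from __future__ import annotations

import logging
import xml.etree.ElementTree as ET
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .errors import DermspecError, InvalidBoxError

__all__ = [
    "Box",
    "AnnotatedImage",
    "YoloLabel",
    "resize_with_boxes",
    "voc_to_yolo",
    "yolo_to_voc",
    "split_dataset",
    "read_voc_xml",
    "write_voc_xml",
    "read_yolo_txt",
    "write_yolo_txt",
    "read_class_list",
    "write_class_list",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Box:
    class_label: str
    xmin: float
    ymin: float
    xmax: float
    ymax: float

    def validate(self, width: float, height: float) -> None:
        if not (0 <= self.xmin < self.xmax <= width):
            raise InvalidBoxError(f"x extent {self.xmin}..{self.xmax} invalid for width {width}")
        if not (0 <= self.ymin < self.ymax <= height):
            raise InvalidBoxError(f"y extent {self.ymin}..{self.ymax} invalid for height {height}")


@dataclass
class AnnotatedImage:
    image_id: str
    width: int
    height: int
    boxes: list[Box] = field(default_factory=list)
    image: np.ndarray | None = None  # H x W x 3 uint8, optional

    def __post_init__(self) -> None:
        for box in self.boxes:
            box.validate(self.width, self.height)
        if self.image is not None and self.image.shape[:2] != (self.height, self.width):
            raise DermspecError("pixel data does not match the declared size")

    def majority_class(self) -> str:
        if not self.boxes:
            raise DermspecError(f"{self.image_id}: no boxes")
        counts = Counter(b.class_label for b in self.boxes)
        top = max(counts.values())
        # deterministic tie-break: lexicographically first among the modes
        return min(label for label, c in counts.items() if c == top)


@dataclass(frozen=True)
class YoloLabel:
    """Normalized center-size label; all coordinates in (0, 1]."""

    class_index: int
    cx: float
    cy: float
    w: float
    h: float

    def __post_init__(self) -> None:
        tol = 1e-6
        for name in ("cx", "cy", "w", "h"):
            v = getattr(self, name)
            if not 0 < v <= 1 + tol:
                raise InvalidBoxError(f"{name}={v} outside (0, 1]")
        if not (-tol <= self.cx - self.w / 2 and self.cx + self.w / 2 <= 1 + tol):
            raise InvalidBoxError("box overflows image in x")
        if not (-tol <= self.cy - self.h / 2 and self.cy + self.h / 2 <= 1 + tol):
            raise InvalidBoxError("box overflows image in y")


def resize_with_boxes(item: AnnotatedImage, target: int = 640) -> AnnotatedImage:
    """Anisotropic resize to target x target; boxes scale per axis.

    Boxes that collapse to zero area after scaling and rounding are
    dropped with a warning.
    """
    if target < 32:
        raise DermspecError("target size must be >= 32")
    sx = target / item.width
    sy = target / item.height
    boxes = []
    for box in item.boxes:
        scaled = Box(box.class_label, box.xmin * sx, box.ymin * sy, box.xmax * sx, box.ymax * sy)
        if round(scaled.xmax) - round(scaled.xmin) < 1 or round(scaled.ymax) - round(scaled.ymin) < 1:
            log.warning("%s: dropping degenerate box %s after resize", item.image_id, box)
            continue
        boxes.append(scaled)
    image = item.image
    if image is not None:
        image = np.asarray(
            Image.fromarray(image).resize((target, target), Image.Resampling.BILINEAR)
        )
    return AnnotatedImage(item.image_id, target, target, boxes, image)


def voc_to_yolo(box: Box, image_width: float, image_height: float, class_list: list[str]) -> YoloLabel:
    """Pixel box -> normalized YOLO center-size label."""
    box.validate(image_width, image_height)
    try:
        index = class_list.index(box.class_label)
    except ValueError:
        raise DermspecError(f"class {box.class_label!r} not in class list") from None
    return YoloLabel(
        index,
        (box.xmin + box.xmax) / 2 / image_width,
        (box.ymin + box.ymax) / 2 / image_height,
        (box.xmax - box.xmin) / image_width,
        (box.ymax - box.ymin) / image_height,
    )


def yolo_to_voc(label: YoloLabel, image_width: float, image_height: float, class_list: list[str]) -> Box:
    return Box(
        class_list[label.class_index],
        (label.cx - label.w / 2) * image_width,
        (label.cy - label.h / 2) * image_height,
        (label.cx + label.w / 2) * image_width,
        (label.cy + label.h / 2) * image_height,
    )


def split_dataset(
    items: list[AnnotatedImage], train_fraction: float = 0.8, seed: int = 0
) -> tuple[list[AnnotatedImage], list[AnnotatedImage]]:
    """Deterministic stratified split by each image's majority class.

    Per class, train count = round(train_fraction * n_class).
    """
    if not 0 < train_fraction < 1:
        raise DermspecError("train_fraction must lie in (0, 1)")
    by_class: dict[str, list[AnnotatedImage]] = {}
    for item in items:
        by_class.setdefault(item.majority_class(), []).append(item)
    for label, members in by_class.items():
        if len(members) < 2:
            raise DermspecError(f"class {label!r} has < 2 items; cannot stratify")
    rng = np.random.default_rng(seed)
    train: list[AnnotatedImage] = []
    test: list[AnnotatedImage] = []
    for label in sorted(by_class):
        members = by_class[label]
        order = rng.permutation(len(members))
        n_train = int(round(train_fraction * len(members)))
        train += [members[i] for i in order[:n_train]]
        test += [members[i] for i in order[n_train:]]
    return train, test


# --- Pascal-VOC XML ------------------------------------------------------

def read_voc_xml(path: str | Path) -> AnnotatedImage:
    """Read a VOC annotation; 1-based inclusive pixels -> 0-based half-open."""
    root = ET.parse(str(path)).getroot()
    size = root.find("size")
    width = int(size.findtext("width"))
    height = int(size.findtext("height"))
    image_id = Path(root.findtext("filename", default=Path(path).stem)).stem
    boxes = []
    for obj in root.iter("object"):
        bnd = obj.find("bndbox")
        boxes.append(
            Box(
                obj.findtext("name"),
                float(bnd.findtext("xmin")) - 1,
                float(bnd.findtext("ymin")) - 1,
                float(bnd.findtext("xmax")),
                float(bnd.findtext("ymax")),
            )
        )
    return AnnotatedImage(image_id, width, height, boxes)


def write_voc_xml(item: AnnotatedImage, path: str | Path) -> None:
    root = ET.Element("annotation")
    ET.SubElement(root, "filename").text = f"{item.image_id}.png"
    size = ET.SubElement(root, "size")
    ET.SubElement(size, "width").text = str(item.width)
    ET.SubElement(size, "height").text = str(item.height)
    ET.SubElement(size, "depth").text = "3"
    for box in item.boxes:
        obj = ET.SubElement(root, "object")
        ET.SubElement(obj, "name").text = box.class_label
        bnd = ET.SubElement(obj, "bndbox")
        ET.SubElement(bnd, "xmin").text = str(int(round(box.xmin)) + 1)
        ET.SubElement(bnd, "ymin").text = str(int(round(box.ymin)) + 1)
        ET.SubElement(bnd, "xmax").text = str(int(round(box.xmax)))
        ET.SubElement(bnd, "ymax").text = str(int(round(box.ymax)))
    ET.indent(tree := ET.ElementTree(root))
    tree.write(str(path), encoding="unicode")


# --- YOLO txt ------------------------------------------------------------

def write_yolo_txt(labels: list[YoloLabel], path: str | Path) -> None:
    lines = [
        f"{lab.class_index} {lab.cx:.6f} {lab.cy:.6f} {lab.w:.6f} {lab.h:.6f}"
        for lab in labels
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_yolo_txt(path: str | Path) -> list[YoloLabel]:
    labels = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        idx, cx, cy, w, h = line.split()
        labels.append(YoloLabel(int(idx), float(cx), float(cy), float(w), float(h)))
    return labels


def write_class_list(class_list: list[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(class_list) + "\n")


def read_class_list(path: str | Path) -> list[str]:
    return [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]
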