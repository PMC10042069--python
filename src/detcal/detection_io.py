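"""Domain types and file formats for detection evaluation and calibration.

All geometry lives in one internal convention: continuous pixel coordinates,
origin at the image's top-left corner, x rightward, y downward, boxes stored
corner-form ``[x_min, y_min, x_max, y_max]``. The YOLO normalized-center form
(``class cx cy w h``) is used only at the file boundary.

Three interchange formats are supported:

* YOLO-txt ground-truth annotations, one file per image;
* COCO-style JSON detection lists (``image_id, category_id, bbox, score``);
* a flat CSV of calibration records linking each prediction's features to
  its binary correctness flag.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

RECORDS_CSV_COLUMNS = ["image_id", "class_id", "confidence", "cx_norm", "cy_norm", "z"]


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class BBox:
    """Axis-aligned rectangle in pixel coordinates (x right, y down)."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        vals = (self.x_min, self.y_min, self.x_max, self.y_max)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError(f"non-finite box coordinates: {vals}")
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise ValueError(f"degenerate box (needs x_max > x_min, y_max > y_min): {vals}")

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.x_min + self.x_max), 0.5 * (self.y_min + self.y_max))


@dataclass(frozen=True)
class GroundTruthBox:
    """An annotated box of a given class on a given image."""

    image_id: str
    class_id: int
    box: BBox

    def __post_init__(self) -> None:
        if not self.image_id:
            raise ValueError("image_id must be non-empty")
        if self.class_id < 0:
            raise ValueError(f"class_id must be >= 0, got {self.class_id}")


@dataclass(frozen=True)
class Detection:
    """A predicted box with the detector's confidence score.

    ``calibrated_confidence`` is filled in by the calibration stage; the raw
    ``confidence`` is always preserved alongside.
    """

    image_id: str
    class_id: int
    box: BBox
    confidence: float
    calibrated_confidence: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.image_id:
            raise ValueError("image_id must be non-empty")
        if self.class_id < 0:
            raise ValueError(f"class_id must be >= 0, got {self.class_id}")
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence must be in [0,1], got {self.confidence}")
        if self.calibrated_confidence is not None and not (
            0.0 <= self.calibrated_confidence <= 1.0
        ):
            raise ValueError(
                f"calibrated_confidence must be in [0,1], got {self.calibrated_confidence}"
            )

    def with_calibrated(self, value: float) -> "Detection":
        return replace(self, calibrated_confidence=float(value))


@dataclass
class ImageRecord:
    """Image metadata (and optionally pixels) needed to normalize and augment."""

    image_id: str
    width: int
    height: int
    pixels: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError(f"image dimensions must be >= 1, got {self.width}x{self.height}")
        if self.pixels is not None:
            self.pixels = np.asarray(self.pixels, dtype=float)
            if self.pixels.shape != (self.height, self.width):
                raise ValueError(
                    f"pixel grid shape {self.pixels.shape} != (height, width) "
                    f"({self.height}, {self.width})"
                )


@dataclass(frozen=True)
class CalibrationRecord:
    """One prediction's calibration features plus its correctness flag.

    ``confidence`` is the detector's stated score, ``cx_norm``/``cy_norm`` the
    box center normalized by image width/height, and ``z`` is 1 when the
    prediction matched a same-class ground truth under the IoU criterion.
    """

    image_id: str
    class_id: int
    confidence: float
    cx_norm: float
    cy_norm: float
    z: int
    calibrated_confidence: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence must be in [0,1], got {self.confidence}")
        if not (0.0 <= self.cx_norm <= 1.0 and 0.0 <= self.cy_norm <= 1.0):
            raise ValueError(f"normalized centers must be in [0,1]: {self.cx_norm}, {self.cy_norm}")
        if self.z not in (0, 1):
            raise ValueError(f"z must be 0 or 1, got {self.z}")
        if self.calibrated_confidence is not None and not (
            0.0 <= self.calibrated_confidence <= 1.0
        ):
            raise ValueError(
                f"calibrated_confidence must be in [0,1], got {self.calibrated_confidence}"
            )

    def with_calibrated(self, value: float) -> "CalibrationRecord":
        return replace(self, calibrated_confidence=float(value))


# ---------------------------------------------------------------------------
# YOLO-txt annotations
# ---------------------------------------------------------------------------

def read_yolo_annotations(path: str | Path, image: ImageRecord) -> list[GroundTruthBox]:
    """Read one YOLO-txt annotation file into ground-truth boxes.

    Each non-empty line is ``class cx cy w h`` with normalized values in
    (0, 1]. Boxes are converted to pixel corner form and clipped to the image
    bounds (normalized centers near the border with finite width legitimately
    overhang); a clip is logged, not an error. Order is preserved.
    """
    path = Path(path)
    out: list[GroundTruthBox] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        tokens = line.split()
        if len(tokens) != 5:
            raise ParseError(f"{path}:{lineno}: expected 5 tokens, got {len(tokens)}")
        try:
            class_id = int(tokens[0])
            cx, cy, w, h = (float(t) for t in tokens[1:])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from None
        if class_id < 0:
            raise ParseError(f"{path}:{lineno}: negative class id {class_id}")
        for name, v in (("cx", cx), ("cy", cy), ("w", w), ("h", h)):
            if not (0.0 < v <= 1.0):
                raise ParseError(f"{path}:{lineno}: {name}={v} outside (0,1]")
        x_min = (cx - w / 2) * image.width
        x_max = (cx + w / 2) * image.width
        y_min = (cy - h / 2) * image.height
        y_max = (cy + h / 2) * image.height
        clipped = (x_min < 0 or y_min < 0 or x_max > image.width or y_max > image.height)
        x_min, x_max = max(x_min, 0.0), min(x_max, float(image.width))
        y_min, y_max = max(y_min, 0.0), min(y_max, float(image.height))
        if clipped:
            logger.warning("%s:%d: box clipped to image bounds", path, lineno)
        out.append(GroundTruthBox(image.image_id, class_id, BBox(x_min, y_min, x_max, y_max)))
    return out


def write_yolo_annotations(
    boxes: Sequence[GroundTruthBox], path: str | Path, image: ImageRecord
) -> None:
    """Write ground-truth boxes for one image in YOLO-txt normalized form."""
    lines = []
    for gt in boxes:
        cx = 0.5 * (gt.box.x_min + gt.box.x_max) / image.width
        cy = 0.5 * (gt.box.y_min + gt.box.y_max) / image.height
        w = gt.box.width / image.width
        h = gt.box.height / image.height
        lines.append(f"{gt.class_id} {cx:.10g} {cy:.10g} {w:.10g} {h:.10g}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_yolo_annotation_dir(
    gt_dir: str | Path, images: dict[str, ImageRecord]
) -> list[GroundTruthBox]:
    """Read every ``*.txt`` file in a directory; the filename stem is the image_id."""
    out: list[GroundTruthBox] = []
    for path in sorted(Path(gt_dir).glob("*.txt")):
        stem = path.stem
        if stem not in images:
            raise ParseError(f"no image metadata for annotation file {path.name}")
        out.extend(read_yolo_annotations(path, images[stem]))
    return out


# ---------------------------------------------------------------------------
# COCO-style JSON detections
# ---------------------------------------------------------------------------

def read_detections_json(path: str | Path) -> list[Detection]:
    """Read a COCO-style results list into detections.

    Entries are objects with ``image_id``, ``category_id``,
    ``bbox`` = [x, y, w, h] and ``score``; invalid entries raise (indexed),
    never skipped silently.
    """
    data = json.loads(Path(path).read_text())
    if not isinstance(data, list):
        raise ParseError(f"{path}: top-level JSON value must be an array")
    out: list[Detection] = []
    for i, entry in enumerate(data):
        try:
            x, y, w, h = (float(v) for v in entry["bbox"])
            if w <= 0 or h <= 0:
                raise ValueError(f"nonpositive box size w={w}, h={h}")
            score = float(entry["score"])
            if not (0.0 <= score <= 1.0):
                raise ValueError(f"score {score} outside [0,1]")
            cal = entry.get("calibrated_score")
            det = Detection(
                image_id=str(entry["image_id"]),
                class_id=int(entry["category_id"]),
                box=BBox(x, y, x + w, y + h),
                confidence=score,
                calibrated_confidence=None if cal is None else float(cal),
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ParseError(f"{path}: entry {i}: {exc}") from None
        out.append(det)
    return out


def write_detections_json(detections: Sequence[Detection], path: str | Path) -> None:
    """Write detections as a COCO-style results array (lossless round trip)."""
    entries = []
    for d in detections:
        entry = {
            "image_id": d.image_id,
            "category_id": d.class_id,
            "bbox": [d.box.x_min, d.box.y_min, d.box.width, d.box.height],
            "score": d.confidence,
        }
        if d.calibrated_confidence is not None:
            entry["calibrated_score"] = d.calibrated_confidence
        entries.append(entry)
    Path(path).write_text(json.dumps(entries, indent=1))


# ---------------------------------------------------------------------------
# Calibration-record CSV
# ---------------------------------------------------------------------------

def write_records_csv(records: Sequence[CalibrationRecord], path: str | Path) -> None:
    """Write calibration records with the fixed header
    ``image_id,class_id,confidence,cx_norm,cy_norm,z``."""
    df = pd.DataFrame(
        [
            (r.image_id, r.class_id, r.confidence, r.cx_norm, r.cy_norm, r.z)
            for r in records
        ],
        columns=RECORDS_CSV_COLUMNS,
    )
    df.to_csv(path, index=False, float_format="%.17g")


def read_records_csv(path: str | Path) -> list[CalibrationRecord]:
    """Read a calibration-record CSV; schema and invariants are enforced."""
    df = pd.read_csv(path, dtype={"image_id": str})
    missing = [c for c in RECORDS_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    out: list[CalibrationRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        z = row.z
        if float(z) not in (0.0, 1.0):
            raise ParseError(f"{path}: row {i}: z={z} not in {{0,1}}")
        try:
            out.append(
                CalibrationRecord(
                    image_id=str(row.image_id),
                    class_id=int(row.class_id),
                    confidence=float(row.confidence),
                    cx_norm=float(row.cx_norm),
                    cy_norm=float(row.cy_norm),
                    z=int(z),
                )
            )
        except ValueError as exc:
            raise ParseError(f"{path}: row {i}: {exc}") from None
    return out
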