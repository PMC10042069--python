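"""IoU matching of detections to ground truth, and detection metrics.

Correctness of a prediction is operationalized the standard way: a detection
is a true positive (z = 1) when it can be greedily assigned, in descending
confidence order, an unmatched ground-truth box of the same class on the same
image with IoU at or above the threshold. Duplicate detections of an
already-matched ground truth count as false positives; unmatched ground
truths are false negatives.

From the TP/FP/FN counts, precision = TP/(TP+FP), recall = TP/(TP+FN) and
f1 = 2·P·R/(P+R), with the conservative 0-for-0/0 convention in degenerate
cases.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .detection_io import BBox, CalibrationRecord, Detection, GroundTruthBox


@dataclass(frozen=True)
class MatchResult:
    """Outcome of matching one detection (index into the input list)."""

    detection_index: int
    gt_index: Optional[int]
    z: int
    iou_value: float

    def __post_init__(self) -> None:
        if (self.gt_index is not None) != (self.z == 1):
            raise ValueError("z must be 1 exactly when a ground-truth match is present")


@dataclass(frozen=True)
class DetectionMetrics:
    TP: int
    FP: int
    FN: int
    precision: float
    recall: float
    f1: float


def iou(a: BBox, b: BBox) -> float:
    """Intersection-over-union of two boxes; 0 when disjoint."""
    ix = min(a.x_max, b.x_max) - max(a.x_min, b.x_min)
    iy = min(a.y_max, b.y_max) - max(a.y_min, b.y_min)
    if ix <= 0.0 or iy <= 0.0:
        return 0.0
    inter = ix * iy
    return inter / (a.area + b.area - inter)


def match_detections(
    dets: Sequence[Detection],
    gts: Sequence[GroundTruthBox],
    iou_thresh: float = 0.5,
    conf_thresh: float = 0.0,
) -> tuple[list[MatchResult], DetectionMetrics]:
    """Greedily match detections to ground truths per image and class.

    Detections below ``conf_thresh`` are discarded before matching. Survivors
    are processed in descending confidence (ties broken by input order); each
    takes the unmatched same-class ground truth with highest IoU >= ``iou_thresh``
    (IoU ties broken by lowest ground-truth index). Returns one
    :class:`MatchResult` per surviving detection plus the aggregated counts
    and metrics.
    """
    for name, v in (("iou_thresh", iou_thresh), ("conf_thresh", conf_thresh)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} must be in [0,1], got {v}")

    surviving = [i for i, d in enumerate(dets) if d.confidence >= conf_thresh]
    # stable sort => confidence ties keep input order
    order = sorted(surviving, key=lambda i: -dets[i].confidence)

    gt_by_key: dict[tuple[str, int], list[int]] = {}
    for j, gt in enumerate(gts):
        gt_by_key.setdefault((gt.image_id, gt.class_id), []).append(j)

    matched_gt: set[int] = set()
    results: list[MatchResult] = []
    for i in order:
        d = dets[i]
        best_j, best_iou = None, 0.0
        for j in gt_by_key.get((d.image_id, d.class_id), ()):
            if j in matched_gt:
                continue
            v = iou(d.box, gts[j].box)
            if v >= iou_thresh and v > best_iou:
                best_j, best_iou = j, v
        if best_j is None:
            results.append(MatchResult(i, None, 0, best_iou))
        else:
            matched_gt.add(best_j)
            results.append(MatchResult(i, best_j, 1, best_iou))

    results.sort(key=lambda r: r.detection_index)
    tp = sum(r.z for r in results)
    fp = len(results) - tp
    fn = len(gts) - tp
    return results, detection_metrics(tp, fp, fn)


def detection_metrics(TP: int, FP: int, FN: int) -> DetectionMetrics:
    """Precision, recall and f1 from counts; 0/0 cases are defined as 0."""
    if min(TP, FP, FN) < 0:
        raise ValueError("counts must be nonnegative")
    precision = TP / (TP + FP) if TP + FP > 0 else 0.0
    recall = TP / (TP + FN) if TP + FN > 0 else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
    return DetectionMetrics(TP, FP, FN, precision, recall, f1)


def to_calibration_records(
    dets: Sequence[Detection],
    matches: Sequence[MatchResult],
    image_sizes: Mapping[str, tuple[int, int]],
) -> list[CalibrationRecord]:
    """Turn matched detections into calibration records.

    ``image_sizes`` maps image_id -> (width, height) so box centers can be
    normalized into [0,1]. Ground truths without a detection (FN) carry no
    confidence and never become records.
    """
    out: list[CalibrationRecord] = []
    for m in matches:
        d = dets[m.detection_index]
        if d.image_id not in image_sizes:
            raise KeyError(f"no image size for image_id {d.image_id!r}")
        w, h = image_sizes[d.image_id]
        cx, cy = d.box.center
        out.append(
            CalibrationRecord(
                image_id=d.image_id,
                class_id=d.class_id,
                confidence=d.confidence,
                cx_norm=min(max(cx / w, 0.0), 1.0),
                cy_norm=min(max(cy / h, 0.0), 1.0),
                z=m.z,
            )
        )
    return out
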