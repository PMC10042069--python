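"""Synthetic detection streams with a known true calibration function.

Real evaluation of a calibration pipeline needs detections whose probability
of being correct is known exactly — something no trained detector provides.
The simulator emits ground-truth boxes and detections in two modes:

* ``iou_labeled`` — a physically-motivated pipeline: ground-truth boxes are
  perturbed by localization noise, some are missed, spurious boxes are
  injected, and correctness z is then *labelled by IoU matching* exactly as a
  real evaluation would, so the whole matching -> records -> calibration
  chain is exercised end to end.

* ``posterior_driven`` — each detection's correctness is drawn from a stated
  logistic truth
      P(z=1 | s) = sigmoid(a0 + a_conf·logit(conf)
                           + a_cx·(cx_norm - 0.5) + a_cy·(cy_norm - 0.5)),
  giving an exact oracle for quantitative recovery tests. With a_conf < 1 or
  a0 < 0 the stream is overconfident (stated confidence exceeds empirical
  precision), emulating the miscalibration of real detectors; a_cx != 0 adds
  position-dependent miscalibration, which is what justifies feeding box
  centers to the calibrator.

The generator is deterministic given (config, seed): all randomness flows
through one ``numpy.random.default_rng`` stream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .detection_io import BBox, CalibrationRecord, Detection, GroundTruthBox
from .matching import match_detections, to_calibration_records


@dataclass(frozen=True)
class TruthCoefficients:
    """Coefficients of the logistic true-correctness model."""

    a0: float = -1.0
    a_conf: float = 0.5
    a_cx: float = 2.0
    a_cy: float = 0.0


@dataclass(frozen=True)
class SimulatorConfig:
    """Full description of a synthetic detection stream.

    Box geometry is sampled uniformly: side lengths in ``box_size_range``
    (pixels), centers anywhere that keeps the box inside the image. The
    detection model perturbs each emitted box by Gaussian localization noise,
    drops ground truths with probability ``miss_rate`` and injects
    Poisson(``fp_rate``) false positives per image. Raw confidences follow a
    Beta(``conf_alpha``, ``conf_beta``) distribution — high-skewed by
    default, as post-threshold detector scores are.
    """

    n_images: int = 100
    width: int = 1024
    height: int = 1024
    boxes_per_image: int = 3
    box_size_range: tuple[float, float] = (60.0, 220.0)
    loc_noise: float = 8.0
    miss_rate: float = 0.1
    fp_rate: float = 1.0
    conf_alpha: float = 5.0
    conf_beta: float = 2.0
    mode: str = "posterior_driven"
    truth: TruthCoefficients = field(default_factory=TruthCoefficients)
    iou_thresh: float = 0.5
    eps: float = 1e-6

    def __post_init__(self) -> None:
        if self.mode not in ("iou_labeled", "posterior_driven"):
            raise ValueError(f"unknown mode {self.mode!r}")
        for name, v in (("miss_rate", self.miss_rate),):
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.fp_rate < 0 or self.loc_noise < 0:
            raise ValueError("fp_rate and loc_noise must be >= 0")
        lo, hi = self.box_size_range
        if not (0 < lo <= hi):
            raise ValueError(f"invalid box_size_range {self.box_size_range}")
        if hi > min(self.width, self.height):
            raise ValueError(
                f"boxes up to {hi}px cannot fit a {self.width}x{self.height} image"
            )
        if self.n_images < 1 or self.boxes_per_image < 0:
            raise ValueError("n_images must be >= 1 and boxes_per_image >= 0")


@dataclass
class SyntheticDataset:
    """Generated stream plus, in posterior-driven mode, the latent truth."""

    config: SimulatorConfig
    ground_truths: list[GroundTruthBox]
    detections: list[Detection]
    records: list[CalibrationRecord]
    latent_posterior: Optional[np.ndarray]  # per record, posterior-driven mode only

    @property
    def image_sizes(self) -> dict[str, tuple[int, int]]:
        c = self.config
        return {f"img{i:05d}": (c.width, c.height) for i in range(c.n_images)}


def _logit(p: float, eps: float) -> float:
    p = min(max(p, eps), 1.0 - eps)
    return math.log(p / (1.0 - p))


def true_posterior(config: SimulatorConfig, conf: float, cx_norm: float, cy_norm: float) -> float:
    """Evaluate the configured logistic truth P(z=1 | s); posterior-driven only."""
    if config.mode != "posterior_driven":
        raise ValueError("true_posterior is only defined in posterior_driven mode")
    a = config.truth
    eta = (
        a.a0
        + a.a_conf * _logit(conf, config.eps)
        + a.a_cx * (cx_norm - 0.5)
        + a.a_cy * (cy_norm - 0.5)
    )
    return 1.0 / (1.0 + math.exp(-eta))


def _sample_box(rng: np.random.Generator, config: SimulatorConfig) -> BBox:
    lo, hi = config.box_size_range
    w = rng.uniform(lo, hi)
    h = rng.uniform(lo, hi)
    x0 = rng.uniform(0.0, config.width - w)
    y0 = rng.uniform(0.0, config.height - h)
    return BBox(x0, y0, x0 + w, y0 + h)


def _perturb_box(rng: np.random.Generator, box: BBox, noise: float, config: SimulatorConfig) -> BBox:
    if noise == 0.0:
        return box
    for _ in range(50):
        dx, dy, dw, dh = rng.normal(0.0, noise, size=4)
        w = max(box.width + dw, 2.0)
        h = max(box.height + dh, 2.0)
        cx = box.center[0] + dx
        cy = box.center[1] + dy
        x0 = min(max(cx - w / 2, 0.0), config.width - w)
        y0 = min(max(cy - h / 2, 0.0), config.height - h)
        if w > 0 and h > 0:
            return BBox(x0, y0, x0 + w, y0 + h)
    return box


def generate_dataset(config: SimulatorConfig, seed: int = 0) -> SyntheticDataset:
    """Generate a synthetic dataset; identical (config, seed) gives identical output."""
    rng = np.random.default_rng(seed)
    gts: list[GroundTruthBox] = []
    dets: list[Detection] = []

    for i in range(config.n_images):
        image_id = f"img{i:05d}"
        for _ in range(config.boxes_per_image):
            gt_box = _sample_box(rng, config)
            gts.append(GroundTruthBox(image_id, 0, gt_box))
            if rng.uniform() >= config.miss_rate:
                det_box = _perturb_box(rng, gt_box, config.loc_noise, config)
                conf = float(rng.beta(config.conf_alpha, config.conf_beta))
                dets.append(Detection(image_id, 0, det_box, conf))
        n_fp = rng.poisson(config.fp_rate)
        for _ in range(int(n_fp)):
            fp_box = _sample_box(rng, config)
            # spurious boxes: low-mean confidence distribution
            conf = float(rng.beta(2.0, 4.0))
            dets.append(Detection(image_id, 0, fp_box, conf))

    image_sizes = {f"img{i:05d}": (config.width, config.height) for i in range(config.n_images)}

    if config.mode == "iou_labeled":
        # z comes from IoU matching, exactly as a real evaluation would assign it
        matches, _ = match_detections(dets, gts, iou_thresh=config.iou_thresh, conf_thresh=0.0)
        records = to_calibration_records(dets, matches, image_sizes)
        return SyntheticDataset(config, gts, dets, records, None)

    # posterior-driven: correctness drawn from the stated logistic truth
    records: list[CalibrationRecord] = []
    latent = np.empty(len(dets))
    for k, det in enumerate(dets):
        w, h = image_sizes[det.image_id]
        cx, cy = det.box.center
        cxn, cyn = cx / w, cy / h
        p = true_posterior(config, det.confidence, cxn, cyn)
        latent[k] = p
        z = int(rng.uniform() < p)
        records.append(
            CalibrationRecord(det.image_id, det.class_id, det.confidence, cxn, cyn, z)
        )
    return SyntheticDataset(config, gts, dets, records, latent)
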