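"""Training-set augmentation for OCT B-scans: motion blur and horizontal flip.

Only these two operators exist here, deliberately: OCT light propagates in a
fixed (axial) direction, so vertical flips and rotations would change the
physical nature of the image. Motion blur emulates the degradation caused by
sample and probe movement during acquisition; the horizontal flip is a
physically valid left-right mirroring whose box annotations are remapped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from .detection_io import BBox, ImageRecord


@dataclass(frozen=True)
class MotionBlurKernel:
    """Normalized line kernel of length L (odd) at angle theta (degrees CCW)."""

    length: int
    angle_deg: float
    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (self.length, self.length):
            raise ValueError(f"kernel grid must be {self.length}x{self.length}, got {w.shape}")
        if (w < 0).any() or not math.isclose(w.sum(), 1.0, rel_tol=0, abs_tol=1e-12):
            raise ValueError("kernel weights must be nonnegative and sum to 1")


def motion_blur_kernel(length: int, angle_deg: float = 0.0) -> MotionBlurKernel:
    """Anti-aliased line kernel: per-cell weight falls off linearly with the
    perpendicular distance to the line through the grid center, then the grid
    is normalized to unit sum."""
    if length < 1 or length % 2 == 0:
        raise ValueError(f"kernel length must be an odd integer >= 1, got {length}")
    if length == 1:
        return MotionBlurKernel(1, angle_deg, np.ones((1, 1)))
    c = (length - 1) / 2
    theta = math.radians(angle_deg)
    # unit direction of the blur line; y axis points down in image coords
    ux, uy = math.cos(theta), -math.sin(theta)
    yy, xx = np.mgrid[0:length, 0:length]
    dx, dy = xx - c, yy - c
    along = dx * ux + dy * uy
    perp = np.abs(dx * (-uy) + dy * ux)
    w = np.clip(1.0 - perp, 0.0, 1.0)
    w[np.abs(along) > c + 0.5] = 0.0  # restrict to a segment of length L
    w = w / w.sum()
    return MotionBlurKernel(length, angle_deg, w)


def motion_blur(image: ImageRecord, length: int = 9, angle_deg: float = 0.0) -> ImageRecord:
    """Convolve the image with a normalized line kernel; borders replicate edges."""
    if image.pixels is None:
        raise ValueError("image has no pixel data")
    kernel = motion_blur_kernel(length, angle_deg)
    blurred = ndimage.convolve(image.pixels, kernel.weights, mode="nearest")
    return ImageRecord(image.image_id, image.width, image.height, blurred)


def horizontal_flip(
    image: ImageRecord, boxes: Sequence[BBox] = ()
) -> tuple[ImageRecord, list[BBox]]:
    """Mirror the image left-right and remap boxes; an involution."""
    pixels = None if image.pixels is None else image.pixels[:, ::-1].copy()
    flipped = ImageRecord(image.image_id, image.width, image.height, pixels)
    W = image.width
    out_boxes = [BBox(W - b.x_max, b.y_min, W - b.x_min, b.y_max) for b in boxes]
    return flipped, out_boxes
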