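import numpy as np
import pytest

from detcal.detection_io import BBox, CalibrationRecord, Detection, GroundTruthBox


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_box(rng, width=100.0, height=100.0, min_side=5.0, max_side=40.0) -> BBox:
    w = rng.uniform(min_side, max_side)
    h = rng.uniform(min_side, max_side)
    x0 = rng.uniform(0, width - w)
    y0 = rng.uniform(0, height - h)
    return BBox(x0, y0, x0 + w, y0 + h)


def random_grid_box(rng, width=100.0, height=100.0, min_side=5.0, max_side=40.0) -> BBox:
    """Random box with coordinates on a 1/1024-pixel grid (dyadic, hence
    exactly representable in binary floating point, as real annotations are)."""
    b = random_box(rng, width, height, min_side, max_side)
    q = lambda v: round(v * 1024) / 1024
    return BBox(q(b.x_min), q(b.y_min), q(b.x_max), q(b.y_max))


def random_records(rng, n, image_id="img", class_id=0):
    """Records with confidence ~ U(0,1) and z ~ Bernoulli(confidence)."""
    conf = rng.uniform(0, 1, n)
    z = (rng.uniform(0, 1, n) < conf).astype(int)
    cx = rng.uniform(0, 1, n)
    cy = rng.uniform(0, 1, n)
    return [
        CalibrationRecord(image_id, class_id, float(c), float(x), float(y), int(zz))
        for c, x, y, zz in zip(conf, cx, cy, z)
    ]


@pytest.fixture
def random_scene(rng):
    """A small random scene of detections and ground truths on one image."""

    def make(n_det, n_gt, seed=None):
        r = np.random.default_rng(seed) if seed is not None else rng
        gts = [GroundTruthBox("im", 0, random_box(r)) for _ in range(n_gt)]
        dets = [
            Detection("im", 0, random_box(r), float(r.uniform(0, 1)))
            for _ in range(n_det)
        ]
        return dets, gts

    return make
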