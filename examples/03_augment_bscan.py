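"""Apply the two OCT-safe augmentation operators to a toy B-scan.

Motion blur emulates acquisition-time sample/probe movement; the horizontal
flip mirrors the image and remaps its boxes. Vertical flips and rotations are
deliberately absent: OCT light propagates in a fixed axial direction.
"""

import numpy as np

from detcal import BBox, ImageRecord, horizontal_flip, motion_blur

rng = np.random.default_rng(0)
pixels = rng.uniform(0, 255, (64, 96))
pixels[20:40, 30:60] += 80  # a bright "calcification-like" patch
image = ImageRecord("bscan", 96, 64, pixels)
boxes = [BBox(30, 20, 60, 40)]

blurred = motion_blur(image, length=9, angle_deg=0.0)
print(f"motion blur L=9, angle=0: intensity sum {image.pixels.sum():.1f} -> "
      f"{blurred.pixels.sum():.1f} (redistributed, not lost)")

flipped, flipped_boxes = horizontal_flip(image, boxes)
print(f"horizontal flip: box {boxes[0]} -> {flipped_boxes[0]}")
back, back_boxes = horizontal_flip(flipped, flipped_boxes)
print(f"flip twice returns the original box: {back_boxes[0] == boxes[0]}")
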