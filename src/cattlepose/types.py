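"""Shared lightweight value types."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class KeypointInstance:
    """One cattle instance: pixel box, confidence, 16 ordered keypoints.

    box is (x, y, w, h) with (x, y) the top-left corner, in pixels.
    keypoints is a (16, 3) array of (x, y, v) with v in {0, 1, 2}:
    0 = not labeled, 1 = labeled but occluded, 2 = visible.  OKS treats
    v > 0 as observed.
    """

    box: tuple[float, float, float, float]
    score: float
    keypoints: np.ndarray

    def __post_init__(self):
        self.keypoints = np.asarray(self.keypoints, dtype=np.float64)
        if self.keypoints.shape != (16, 3):
            raise ValueError("expected 16 keypoints of (x, y, v)")

    @property
    def area(self) -> float:
        return float(self.box[2] * self.box[3])

    def visible_mask(self) -> np.ndarray:
        return self.keypoints[:, 2] > 0
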