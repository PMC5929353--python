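"""Threshold spotfinder baseline and count-threshold hit classifier.

A pixel is *strong* when it is trusted, exceeds the global ADU threshold,
and exceeds its local background by ``sigma_strong`` times the larger of the
local standard deviation and the expected photon shot noise
``sqrt(gain * local_mean)``.  Local statistics are computed over a square
window excluding the pixel itself and all untrusted pixels.  Strong pixels
are grouped by 4-connectivity; groups meeting the minimum area become spot
candidates.  An image is classified Hit when the candidate count reaches the
count threshold (non-strict boundary: count == threshold is a Hit).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import label as cc_label
from scipy.ndimage import uniform_filter

from braggscreen.io_formats import DetectorFrame, FrameStack, Label

__all__ = [
    "SpotfinderParams",
    "SpotCandidate",
    "find_spots",
    "count_threshold_classify",
    "classify_stack",
]

FOUR_CONNECTED = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
EIGHT_CONNECTED = np.ones((3, 3), dtype=int)


@dataclass
class SpotfinderParams:
    """Tunable spotfinder knobs (per-experiment, tuned by inspection)."""

    gain: float = 1.0  # ADU per photon
    global_threshold: float = 100.0  # ADU
    sigma_strong: float = 3.0
    min_spot_area: int = 2  # pixels
    local_window: int = 7
    count_threshold: int = 10
    connectivity: int = 4

    def __post_init__(self) -> None:
        for name in ("gain", "global_threshold", "sigma_strong"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.min_spot_area < 1:
            raise ValueError("min_spot_area must be >= 1")
        if self.local_window < 3 or self.local_window % 2 == 0:
            raise ValueError("local_window must be odd and >= 3")
        if self.count_threshold < 1:
            raise ValueError("count_threshold must be >= 1")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


@dataclass
class SpotCandidate:
    """One connected group of strong pixels."""

    pixel_members: list[tuple[int, int]]
    centroid: tuple[float, float]
    peak_value: float
    area: int


def _local_background(
    image: np.ndarray, mask: np.ndarray, window: int
) -> tuple[np.ndarray, np.ndarray]:
    """Mean/std of trusted pixels in each window, excluding the center pixel."""
    m = mask.astype(np.float64)
    area = float(window * window)
    cnt = uniform_filter(m, size=window, mode="reflect") * area - m
    s1 = uniform_filter(image * m, size=window, mode="reflect") * area - image * m
    s2 = (
        uniform_filter(image * image * m, size=window, mode="reflect") * area
        - image * image * m
    )
    cnt_safe = np.maximum(cnt, 1.0)
    mean = s1 / cnt_safe
    var = np.maximum(s2 / cnt_safe - mean * mean, 0.0)
    return mean, np.sqrt(var)


def strong_pixel_mask(frame: DetectorFrame, params: SpotfinderParams) -> np.ndarray:
    """Boolean grid of pixels passing both threshold tests."""
    image = frame.pixels.astype(np.float64)
    mask = frame.mask
    if params.local_window > min(image.shape):
        raise ValueError(
            f"local_window {params.local_window} larger than frame {image.shape}"
        )
    mean, std = _local_background(image, mask, params.local_window)
    shot = np.sqrt(params.gain * np.maximum(mean, 0.0))
    noise = np.maximum(std, shot)
    return (
        mask
        & (image > params.global_threshold)
        & (image - mean > params.sigma_strong * noise)
    )


def find_spots(frame: DetectorFrame, params: SpotfinderParams) -> list[SpotCandidate]:
    """Spot candidates sorted by descending peak value."""
    strong = strong_pixel_mask(frame, params)
    structure = FOUR_CONNECTED if params.connectivity == 4 else EIGHT_CONNECTED
    labels, n = cc_label(strong, structure=structure)
    image = frame.pixels
    out: list[SpotCandidate] = []
    for i in range(1, n + 1):
        rows, cols = np.nonzero(labels == i)
        area = len(rows)
        if area < params.min_spot_area:
            continue
        vals = image[rows, cols]
        out.append(
            SpotCandidate(
                pixel_members=list(zip(rows.tolist(), cols.tolist())),
                centroid=(float(rows.mean()), float(cols.mean())),
                peak_value=float(vals.max()),
                area=area,
            )
        )
    out.sort(key=lambda c: -c.peak_value)
    return out


def count_threshold_classify(
    frame: DetectorFrame, params: SpotfinderParams
) -> tuple[int, Label]:
    """Binary baseline decision: Hit iff candidate count >= count_threshold."""
    count = len(find_spots(frame, params))
    label = Label.HIT if count >= params.count_threshold else Label.MISS
    return count, label


def classify_stack(
    stack: FrameStack, params: SpotfinderParams
) -> list[tuple[str, int, Label]]:
    """Per-frame (frame_id, candidate count, binary label) for a whole stack."""
    return [
        (frame.frame_id, *count_threshold_classify(frame, params)) for frame in stack
    ]
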