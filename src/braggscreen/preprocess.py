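"""Image conditioning: correction, binning, cropping, normalization.

The contrast pipeline is global standardization (zero mean, unit standard
deviation over trusted pixels) followed by local contrast normalization
(LCN): each pixel is re-standardized by the mean and standard deviation of
its square neighborhood, with the denominator floored at ``epsilon``.
Untrusted pixels stay zero in the output and are excluded from every
statistic.  A linear-contrast comparator ``D = min(1, M * P_x / P90)`` is
provided for ablation studies.

Binning SUMS factor x factor blocks (photon preserving); the overall scale
difference versus averaging is absorbed by global normalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter

from braggscreen.io_formats import DetectorFrame, FrameStack

__all__ = [
    "DegenerateInputError",
    "LCNParams",
    "CropSpec",
    "GlobalNormStats",
    "correct_frame",
    "bin_image",
    "bin_mask",
    "crop",
    "augment",
    "global_normalize",
    "local_contrast_normalize",
    "full_lcn",
    "linear_contrast",
    "preprocess_frame",
    "preprocess_stack",
]


class DegenerateInputError(ValueError):
    """Input lacks the variation the operation needs (e.g. constant image)."""


@dataclass
class LCNParams:
    """Square-neighborhood size and variance floor for LCN."""

    window: int = 9
    epsilon: float = 1e-4

    def __post_init__(self) -> None:
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError(f"window must be odd and >= 3, got {self.window}")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


@dataclass
class CropSpec:
    """Output size, shift range and mode for (center|random) cropping."""

    size: int
    max_shift: int = 0
    mode: str = "center"

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError("crop size must be positive")
        if self.max_shift < 0:
            raise ValueError("max_shift must be nonnegative")
        if self.mode not in ("center", "random"):
            raise ValueError(f"mode must be 'center' or 'random', got {self.mode!r}")


@dataclass
class GlobalNormStats:
    """Mean/std of the trusted pixels of one image (population sigma)."""

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")


def correct_frame(
    raw: DetectorFrame,
    dark: DetectorFrame | None = None,
    gain_map: np.ndarray | None = None,
) -> DetectorFrame:
    """Dark subtraction and per-pixel gain scaling on trusted pixels.

    Negative results of dark subtraction are preserved.  With neither dark
    nor gain this is the identity.
    """
    pixels = raw.pixels.astype(np.float64)
    if dark is not None:
        if dark.shape != raw.shape:
            raise ValueError(f"dark shape {dark.shape} != raw shape {raw.shape}")
        pixels = pixels - dark.pixels
    if gain_map is not None:
        gain_map = np.asarray(gain_map, dtype=np.float64)
        if gain_map.shape != raw.pixels.shape:
            raise ValueError(
                f"gain map shape {gain_map.shape} != raw shape {raw.shape}"
            )
        pixels = pixels * gain_map
    return DetectorFrame(
        pixels=np.where(raw.mask, pixels, 0.0),
        mask=raw.mask,
        beam_center=raw.beam_center,
        frame_id=raw.frame_id,
    )


def bin_image(image: np.ndarray, factor: int) -> np.ndarray:
    """Sum factor x factor blocks; trailing rows/cols that do not fill a
    block are trimmed from the high end."""
    if factor < 1:
        raise ValueError(f"bin factor must be >= 1, got {factor}")
    image = np.asarray(image)
    if factor == 1:
        return image.copy()
    h, w = image.shape
    hh, ww = (h // factor) * factor, (w // factor) * factor
    trimmed = image[:hh, :ww].astype(np.float64)
    return trimmed.reshape(hh // factor, factor, ww // factor, factor).sum(axis=(1, 3))


def bin_mask(mask: np.ndarray, factor: int) -> np.ndarray:
    """Binned trust mask: a block is trusted when at least half its pixels are."""
    if factor == 1:
        return np.asarray(mask, dtype=bool).copy()
    counts = bin_image(np.asarray(mask, dtype=np.float64), factor)
    return counts >= (factor * factor) / 2.0


def crop(
    image: np.ndarray,
    beam_center: tuple[float, float],
    spec: CropSpec,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Extract a size x size window around the beam center.

    Random mode offsets the window center by independent integer shifts
    uniform on [-max_shift, +max_shift]; the window is clamped to the image
    boundary so it never reads outside.
    """
    image = np.asarray(image)
    h, w = image.shape
    if spec.size > min(h, w):
        raise ValueError(f"crop size {spec.size} larger than image {h}x{w}")
    cr, cc = int(round(beam_center[0])), int(round(beam_center[1]))
    if spec.mode == "random":
        if rng is None:
            raise ValueError("random cropping requires an rng")
        cr += int(rng.integers(-spec.max_shift, spec.max_shift + 1))
        cc += int(rng.integers(-spec.max_shift, spec.max_shift + 1))
    r0 = min(max(cr - spec.size // 2, 0), h - spec.size)
    c0 = min(max(cc - spec.size // 2, 0), w - spec.size)
    return image[r0: r0 + spec.size, c0: c0 + spec.size].copy()


def augment(
    image: np.ndarray,
    rng: np.random.Generator,
    flips: bool = True,
    max_shift: int = 0,
    scale_range: tuple[float, float] = (1.0, 1.0),
) -> np.ndarray:
    """Training-time augmentation: optional flips, integer shift, intensity scale.

    Applied in order: horizontal flip (prob 0.5), vertical flip (prob 0.5),
    integer translation with zero fill, multiplicative scale drawn uniformly
    from ``scale_range``.  Deterministic given the rng state.
    """
    lo, hi = scale_range
    if lo <= 0 or hi < lo:
        raise ValueError(f"scale_range must satisfy 0 < lo <= hi, got {scale_range}")
    out = np.asarray(image, dtype=np.float64).copy()
    if flips:
        if rng.random() < 0.5:
            out = out[:, ::-1]
        if rng.random() < 0.5:
            out = out[::-1, :]
    if max_shift > 0:
        dr = int(rng.integers(-max_shift, max_shift + 1))
        dc = int(rng.integers(-max_shift, max_shift + 1))
        shifted = np.zeros_like(out)
        h, w = out.shape
        r_src = slice(max(0, -dr), min(h, h - dr))
        c_src = slice(max(0, -dc), min(w, w - dc))
        r_dst = slice(max(0, dr), min(h, h + dr))
        c_dst = slice(max(0, dc), min(w, w + dc))
        shifted[r_dst, c_dst] = out[r_src, c_src]
        out = shifted
    scale = lo if hi == lo else float(rng.uniform(lo, hi))
    return out * scale


def global_normalize(
    image: np.ndarray, mask: np.ndarray | None = None
) -> tuple[np.ndarray, GlobalNormStats]:
    """Standardize to zero mean / unit population sigma over trusted pixels."""
    image = np.asarray(image, dtype=np.float64)
    if mask is None:
        mask = np.ones_like(image, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    vals = image[mask]
    if vals.size < 2:
        raise DegenerateInputError("need at least 2 trusted pixels")
    mu = float(vals.mean())
    sigma = float(vals.std())
    if sigma == 0.0:
        raise DegenerateInputError("image has zero variance over trusted pixels")
    out = np.where(mask, (image - mu) / sigma, 0.0)
    return out, GlobalNormStats(mu=mu, sigma=sigma)


def _masked_window_stats(
    image: np.ndarray, mask: np.ndarray, window: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-pixel count, mean and std over the trusted pixels of each window.

    Boundary windows see reflection padding (scipy 'reflect', i.e. edge
    value included) of both image and mask.
    """
    m = mask.astype(np.float64)
    area = float(window * window)
    cnt = uniform_filter(m, size=window, mode="reflect") * area
    s1 = uniform_filter(image * m, size=window, mode="reflect") * area
    s2 = uniform_filter(image * image * m, size=window, mode="reflect") * area
    cnt_safe = np.maximum(cnt, 1e-12)
    mean = s1 / cnt_safe
    var = np.maximum(s2 / cnt_safe - mean * mean, 0.0)
    return cnt, mean, np.sqrt(var)


def local_contrast_normalize(
    image: np.ndarray,
    mask: np.ndarray | None = None,
    params: LCNParams | None = None,
) -> np.ndarray:
    """Per-pixel standardization by neighborhood mean/std of trusted pixels.

    Expects a globally normalized input (see :func:`full_lcn` for the
    composed pipeline).  Output is ``(v - mean_local) / max(std_local,
    epsilon)``; untrusted pixels are zero.
    """
    params = params or LCNParams()
    image = np.asarray(image, dtype=np.float64)
    if mask is None:
        mask = np.ones_like(image, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if params.window > min(image.shape):
        raise ValueError(
            f"window {params.window} larger than image {image.shape}"
        )
    cnt, mean, std = _masked_window_stats(image, mask, params.window)
    denom = np.maximum(std, params.epsilon)
    out = (image - mean) / denom
    out[cnt < 0.5] = 0.0  # windows with no trusted pixel at all
    return np.where(mask, out, 0.0)


def full_lcn(
    image: np.ndarray,
    mask: np.ndarray | None = None,
    params: LCNParams | None = None,
) -> np.ndarray:
    """Global normalization followed by local contrast normalization."""
    v, _ = global_normalize(image, mask)
    return local_contrast_normalize(v, mask, params)


def linear_contrast(image: np.ndarray, M: float = 0.4,
                    mask: np.ndarray | None = None) -> np.ndarray:
    """Viewer-style display transform ``D = min(1, M * P_x / P90)`` in [0, 1].

    ``P90`` is the 90th-percentile pixel value over trusted pixels; negative
    inputs map to 0.
    """
    image = np.asarray(image, dtype=np.float64)
    if mask is None:
        mask = np.ones_like(image, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    p90 = float(np.percentile(image[mask], 90))
    if p90 <= 0:
        raise DegenerateInputError(f"90th percentile must be positive, got {p90}")
    out = np.clip(M * image / p90, 0.0, 1.0)
    return np.where(mask, out, 0.0)


# ---------------------------------------------------------------------------
# Stack-level pipeline


def preprocess_frame(
    frame: DetectorFrame,
    bin_factor: int = 4,
    crop_spec: CropSpec | None = None,
    contrast: str = "lcn",
    lcn_params: LCNParams | None = None,
    rng: np.random.Generator | None = None,
    augment_cfg: dict | None = None,
) -> np.ndarray:
    """Bin, crop, (optionally augment) and contrast-normalize one frame.

    ``contrast`` is one of ``lcn`` (global + local normalization),
    ``linear`` (viewer transform), ``global`` (global normalization only)
    or ``none`` (raw values).
    """
    img = bin_image(frame.pixels, bin_factor)
    mask = bin_mask(frame.mask, bin_factor)
    center = (frame.beam_center[0] / bin_factor, frame.beam_center[1] / bin_factor)
    if crop_spec is not None:
        # crop image and mask with the same window: reuse one rng draw
        state = rng.bit_generator.state if rng is not None else None
        img = crop(img, center, crop_spec, rng)
        if state is not None and crop_spec.mode == "random":
            rng.bit_generator.state = state
        mask = crop(mask.astype(np.float64), center, crop_spec, rng) >= 0.5
    if augment_cfg:
        if rng is None:
            raise ValueError("augmentation requires an rng")
        img = augment(img, rng, **augment_cfg)
    if contrast == "lcn":
        return full_lcn(img, mask, lcn_params)
    if contrast == "global":
        return global_normalize(img, mask)[0]
    if contrast == "linear":
        return linear_contrast(img, mask=mask)
    if contrast == "none":
        return np.where(mask, img.astype(np.float64), 0.0)
    raise ValueError(f"unknown contrast mode {contrast!r}")


def preprocess_stack(
    stack: FrameStack,
    bin_factor: int = 4,
    crop_size: int | None = None,
    crop_mode: str = "center",
    max_shift: int = 5,
    contrast: str = "lcn",
    lcn_params: LCNParams | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, list[str]]:
    """Apply :func:`preprocess_frame` to a stack.

    Returns the (N, size, size) float array of conditioned images and the
    frame ids in order.
    """
    rng = np.random.default_rng(seed)
    spec = None
    if crop_size is not None:
        spec = CropSpec(size=crop_size, max_shift=max_shift, mode=crop_mode)
    images = []
    ids = []
    for frame in stack:
        images.append(
            preprocess_frame(
                frame,
                bin_factor=bin_factor,
                crop_spec=spec,
                contrast=contrast,
                lcn_params=lcn_params,
                rng=rng,
            )
        )
        ids.append(frame.frame_id)
    return np.stack(images), ids
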