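"""Image preprocessing: median-filter denoising and contrast enhancement.

Histopathology acquisitions routinely carry impulse ("salt and pepper")
noise and, depending on staining and illumination, a compressed dynamic
range.  The pipeline therefore cleans every image with a median filter and
then stretches contrast, either by plain histogram equalization or by CLAHE
(contrast-limited adaptive histogram equalization), before any feature
extraction.

Images are 2-D grayscale or H x W x 3 RGB arrays, integer 0-255 or float
0-1.  All operations preserve dtype family, shape and declared intensity
range, and process RGB images per channel.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage import exposure

from .errors import ParameterError

__all__ = [
    "median_filter",
    "enhance_contrast",
    "to_grayscale",
    "preprocess_image",
]


def _check_image(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim == 3 and image.shape[2] not in (1, 3):
        raise ParameterError(f"expected 1 or 3 channels, got {image.shape[2]}")
    if image.ndim not in (2, 3):
        raise ParameterError(f"expected a 2-D or 3-channel image, got ndim={image.ndim}")
    return image


def _is_integer(image: np.ndarray) -> bool:
    return np.issubdtype(image.dtype, np.integer)


def median_filter(image: np.ndarray, window: int = 3) -> np.ndarray:
    """Median-filter an image with a square ``window x window`` neighborhood.

    Borders are reflect-padded so the output has the same shape as the
    input.  Multi-channel images are filtered channel by channel.  A window
    of 1 is the identity.

    Parameters
    ----------
    image : ndarray
        2-D grayscale or H x W x 3 color image.
    window : int
        Odd side length of the square neighborhood, ``1 <= window <=
        min(height, width)``.
    """
    image = _check_image(image)
    if not isinstance(window, (int, np.integer)) or window < 1 or window % 2 == 0:
        raise ParameterError(f"window must be a positive odd integer, got {window!r}")
    h, w = image.shape[:2]
    if window > min(h, w):
        raise ParameterError(
            f"window {window} exceeds image size {h}x{w}"
        )
    if window == 1:
        return image.copy()
    if image.ndim == 2:
        return ndimage.median_filter(image, size=window, mode="mirror")
    out = np.empty_like(image)
    for c in range(image.shape[2]):
        out[..., c] = ndimage.median_filter(image[..., c], size=window, mode="mirror")
    return out


def _hist_eq_channel_int(channel: np.ndarray, n_levels: int = 256) -> np.ndarray:
    # Integer equalization with the classic "scaled CDF" lookup: a gray
    # level with empirical CDF c maps to round_half_up(c * n_levels) - 1,
    # so a uniform 4-level image lands on {63, 127, 191, 255}.
    counts = np.bincount(channel.ravel(), minlength=n_levels)
    cdf = np.cumsum(counts) / channel.size
    levels = np.floor(cdf * n_levels + 0.5).astype(np.int64) - 1
    np.clip(levels, 0, n_levels - 1, out=levels)
    return levels[channel].astype(channel.dtype)


def _hist_eq_channel_float(channel: np.ndarray) -> np.ndarray:
    # Float images equalize to the empirical CDF itself (range [0, 1]).
    flat = channel.ravel()
    order = np.argsort(flat, kind="stable")
    ranks = np.empty_like(order)
    ranks[order] = np.arange(flat.size)
    # average rank for ties via the CDF of the sorted unique values
    uniq, inv = np.unique(flat, return_inverse=True)
    counts = np.bincount(inv)
    cdf = np.cumsum(counts) / flat.size
    return cdf[inv].reshape(channel.shape).astype(channel.dtype, copy=False)


def enhance_contrast(
    image: np.ndarray,
    method: str = "clahe",
    clip_limit: float = 0.01,
    tile: int = 8,
) -> np.ndarray:
    """Stretch image contrast by histogram equalization or CLAHE.

    ``method="hist_eq"`` applies global histogram equalization;
    ``method="clahe"`` applies contrast-limited adaptive equalization with
    the given ``clip_limit`` and ``tile`` grid size.  Constant images are
    returned unchanged (there is no contrast to stretch), and the output
    never leaves the input's declared intensity range.
    """
    image = _check_image(image)
    if method not in ("hist_eq", "clahe"):
        raise ParameterError(f"unknown contrast method {method!r}")
    if method == "clahe" and (clip_limit <= 0 or tile < 1):
        raise ParameterError("clahe requires clip_limit > 0 and tile >= 1")

    if np.ptp(image) == 0:
        return image.copy()

    integer = _is_integer(image)
    if image.ndim == 3:
        out = np.empty_like(image)
        for c in range(image.shape[2]):
            out[..., c] = enhance_contrast(image[..., c], method, clip_limit, tile)
        return out

    if method == "hist_eq":
        if integer:
            return _hist_eq_channel_int(image.astype(np.int64)).astype(image.dtype)
        return _hist_eq_channel_float(image)

    # CLAHE: skimage works in float [0, 1]; rescale and convert back.
    if integer:
        work = image.astype(np.float64) / 255.0
    else:
        work = image.astype(np.float64)
    kernel = (
        max(1, image.shape[0] // tile),
        max(1, image.shape[1] // tile),
    )
    eq = exposure.equalize_adapthist(work, kernel_size=kernel, clip_limit=clip_limit)
    if integer:
        return np.clip(np.floor(eq * 255.0 + 0.5), 0, 255).astype(image.dtype)
    return np.clip(eq, 0.0, 1.0).astype(image.dtype)


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Collapse an RGB image to grayscale with ITU-R 601 luma weights."""
    image = _check_image(image)
    if image.ndim == 2:
        return image.copy()
    weights = np.array([0.299, 0.587, 0.114])
    gray = image[..., :3].astype(np.float64) @ weights
    if _is_integer(image):
        return np.clip(np.floor(gray + 0.5), 0, 255).astype(image.dtype)
    return gray.astype(image.dtype)


def preprocess_image(
    image: np.ndarray,
    median_window: int = 3,
    contrast: str = "clahe",
    clip_limit: float = 0.01,
    tile: int = 8,
    grayscale: bool = True,
) -> np.ndarray:
    """Denoise, enhance and (optionally) gray-convert a single image."""
    out = median_filter(image, median_window)
    out = enhance_contrast(out, contrast, clip_limit, tile)
    if grayscale:
        out = to_grayscale(out)
    return out
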