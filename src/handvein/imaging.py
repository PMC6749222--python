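"""Grayscale filtering, thresholding and binary morphology primitives.

Shared by both modalities.  Conventions:

* ``GrayImage``  -- 2-D ``uint8`` array, intensities 0-255, (row, col)
  indexing with row 0 at the top.
* ``BinaryImage`` -- 2-D ``bool`` array, ``True`` = object of interest.

All neighbourhood operations replicate the edge row/column beyond the image
border, so a dark frame is never hallucinated around the scan.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import dilation as _sk_dilation
from skimage.morphology import erosion as _sk_erosion

from .errors import ParameterError

__all__ = [
    "mean_filter", "median_filter", "equalize_histogram",
    "global_threshold", "local_threshold", "dilate", "erode",
]


def _as_gray(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 2:
        raise ParameterError("expected a 2-D grayscale image")
    return img


def _check_odd(value: int, name: str) -> None:
    if value < 3 or value % 2 == 0:
        raise ParameterError(f"{name} must be an odd integer >= 3, got {value}")


def _window_mean(img: np.ndarray, size: int) -> np.ndarray:
    """Exact float window mean with edge replication."""
    kernel = np.ones((size, size), dtype=np.float64)
    sums = ndi.correlate(img.astype(np.float64), kernel, mode="nearest")
    return sums / (size * size)


def mean_filter(img: np.ndarray, core_size: int = 3) -> np.ndarray:
    """Replace each pixel by the arithmetic mean of its core-size window.

    The result is rounded to the nearest integer, ties away from zero.
    """
    img = _as_gray(img)
    _check_odd(core_size, "core_size")
    mean = _window_mean(img, core_size)
    return np.floor(mean + 0.5).astype(np.uint8)  # intensities are >= 0


def median_filter(img: np.ndarray, window: int = 3) -> np.ndarray:
    """Window-median smoothing with edge replication."""
    img = _as_gray(img)
    _check_odd(window, "window")
    return ndi.median_filter(img, size=window, mode="nearest")


def equalize_histogram(img: np.ndarray) -> np.ndarray:
    """Cumulative-histogram equalization onto the full 0-255 range.

    The intensity mapping is monotone non-decreasing, so the rank order of
    pixels is preserved.  A constant image is returned unchanged.
    """
    img = _as_gray(img).astype(np.uint8)
    hist = np.bincount(img.ravel(), minlength=256)
    cdf = np.cumsum(hist)
    nonzero = np.nonzero(hist)[0]
    cdf_min = cdf[nonzero[0]]
    total = img.size
    if total == cdf_min:  # single intensity level
        return img.copy()
    lut = np.floor(255.0 * (cdf - cdf_min) / (total - cdf_min) + 0.5)
    lut = np.clip(lut, 0, 255).astype(np.uint8)
    return lut[img]


def global_threshold(img: np.ndarray, t_g: float) -> np.ndarray:
    """Binarize at ``T = mean(img) - t_g``; object where intensity >= T."""
    img = _as_gray(img)
    threshold = float(img.mean()) - t_g
    return img.astype(np.float64) >= threshold


def local_threshold(img: np.ndarray, surrounding: int = 15,
                    t_g: float = 3.0) -> np.ndarray:
    """Adaptive binarization against the window mean.

    Pixel becomes object iff ``f(i,j) >= mu_ij - t_g`` with ``mu_ij`` the
    mean over the ``surrounding`` x ``surrounding`` window (edge
    replication).  A *negative* ``t_g`` demands that the pixel exceed its
    local mean by ``|t_g|``, which is the mode used for dark-band (vein)
    detection on the inverted region of interest.
    """
    img = _as_gray(img)
    _check_odd(surrounding, "surrounding")
    mu = _window_mean(img, surrounding)
    return img.astype(np.float64) >= mu - t_g


def _disk(radius: int) -> np.ndarray:
    """Digital disk in the Chebyshev metric (a (2r+1)² square footprint);
    the L∞ ball is the discretization that lets a radius-1 closing bridge a
    2 px gap, which is what the vein-closing step is for."""
    return np.ones((2 * radius + 1, 2 * radius + 1), dtype=bool)


def dilate(mask: np.ndarray, radius: int = 1) -> np.ndarray:
    """Morphological dilation with a disk structuring element."""
    return _sk_dilation(np.asarray(mask, dtype=bool), _disk(radius))


def erode(mask: np.ndarray, radius: int = 1) -> np.ndarray:
    """Morphological erosion with a disk structuring element."""
    return _sk_erosion(np.asarray(mask, dtype=bool), _disk(radius))
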