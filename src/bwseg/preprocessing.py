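"""Noise suppression, adaptive binarization, and directional erosion.

These three steps precede every projection analysis: smoothing removes
sensor noise, a per-image Otsu threshold separates bright tooth material
from dark gaps/air, and a short directional erosion deletes thin bridges of
foreground that would otherwise fill projection valleys.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .core import BinaryImage, ParameterError, Radiograph


def gaussian_smooth(img: Radiograph, sigma: float = 1.5) -> Radiograph:
    """Convolve with a normalized Gaussian kernel; ``sigma = 0`` is identity."""
    if sigma < 0:
        raise ParameterError(f"sigma must be >= 0, got {sigma}")
    if sigma == 0:
        return img.with_pixels(img.pixels.copy())
    out = ndimage.gaussian_filter(img.pixels, sigma=sigma, mode="nearest")
    return img.with_pixels(np.clip(out, 0.0, 1.0))


def binarize(img: Radiograph) -> BinaryImage:
    """Per-image adaptive binarization by Otsu's threshold.

    Intensities are quantized to 256 levels and the threshold level t is
    chosen to maximize the between-class variance (smallest t on ties);
    foreground (1) is every pixel whose level is >= t — the bright
    tooth/restoration material. The exhaustive scan over integer levels
    keeps the documented ">= threshold" convention exact, which a
    bin-center threshold estimate would not. A constant image has no
    separable classes and yields an all-background mask.
    """
    levels = np.rint(img.pixels * 255.0).astype(np.int64)
    hist = np.bincount(levels.ravel(), minlength=256).astype(np.float64)
    n = levels.size
    cum_n = np.cumsum(hist)  # pixels with level <= k
    cum_s = np.cumsum(hist * np.arange(256))
    # candidate thresholds t = 1..255: background = level < t
    n0 = cum_n[:-1]
    s0 = cum_s[:-1]
    valid = (n0 > 0) & (n0 < n)
    if not valid.any():
        return BinaryImage(np.zeros_like(levels, dtype=np.uint8))
    with np.errstate(divide="ignore", invalid="ignore"):
        m0 = s0 / n0
        m1 = (cum_s[-1] - s0) / (n - n0)
        var = np.where(valid, n0 * (n - n0) * (m0 - m1) ** 2, -np.inf)
    t = int(np.argmax(var)) + 1
    return BinaryImage((levels >= t).astype(np.uint8))


def erode(mask: BinaryImage, orientation: str, length: int) -> BinaryImage:
    """Morphological erosion with a 1D structuring element.

    ``orientation`` is ``"horizontal"`` (1 x length element, thins columns)
    or ``"vertical"`` (length x 1). The out-of-image neighborhood counts as
    background, so foreground touching the border erodes away. ``length``
    must be odd so the element is centered.
    """
    if length < 1 or length % 2 == 0:
        raise ParameterError(f"erosion length must be odd and >= 1, got {length}")
    if orientation == "horizontal":
        structure = np.ones((1, length), dtype=bool)
    elif orientation == "vertical":
        structure = np.ones((length, 1), dtype=bool)
    else:
        raise ParameterError(f"orientation must be 'horizontal' or 'vertical', got {orientation!r}")
    if length == 1:
        return BinaryImage(mask.mask.copy())
    out = ndimage.binary_erosion(mask.mask.astype(bool), structure=structure, border_value=0)
    return BinaryImage(out.astype(np.uint8))


def default_erode_h(width: int) -> int:
    """Default horizontal structuring length for an image of this width."""
    return _force_odd(max(3, round(width / 50)))


def default_erode_v(row_height: int) -> int:
    """Default vertical structuring length for a jaw row of this height."""
    return _force_odd(max(3, round(row_height / 20)))


def _force_odd(n: int) -> int:
    return n if n % 2 == 1 else n + 1
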