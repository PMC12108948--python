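"""Contrast-enhancement operator bank: IAM, HISTEQ, AHE, and chains.

Three point/local operators raise the contrast between restoration
material (bright white), tooth (gray-white) and caries/background (dark):

* IAM — intensity value mapping: saturating linear rescale between two
  percentile anchors, optionally followed by a gamma curve;
* HISTEQ — global histogram equalization via the normalized cumulative
  histogram;
* AHE — contrast-limited adaptive histogram equalization (per-tile
  clipped histograms, bilinear interpolation between tile mappings).

Operators compose left-to-right into chains; the eight named presets are
the untouched original, each single operator, and the ordered pairs/triple
used in the ablation design.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from skimage.exposure import equalize_adapthist

from .core import ParameterError, Radiograph


def apply_iam(img: Radiograph, low_pct: float = 1.0, high_pct: float = 99.0,
              gamma: float = 1.0) -> Radiograph:
    """Percentile-anchored intensity mapping with gamma.

    ``out = clip((in - P_low) / (P_high - P_low), 0, 1) ** gamma`` where
    P_low/P_high are the image's ``low_pct``/``high_pct`` percentile
    intensities. Monotone non-decreasing. A constant image (P_low = P_high)
    maps to all zeros.
    """
    if not (0 <= low_pct < high_pct <= 100):
        raise ParameterError(f"need 0 <= low_pct < high_pct <= 100, got {low_pct}, {high_pct}")
    if gamma <= 0:
        raise ParameterError(f"gamma must be > 0, got {gamma}")
    p_low, p_high = np.percentile(img.pixels, [low_pct, high_pct])
    if p_high == p_low:
        return img.with_pixels(np.zeros_like(img.pixels))
    out = np.clip((img.pixels - p_low) / (p_high - p_low), 0.0, 1.0) ** gamma
    return img.with_pixels(out)


def apply_histeq(img: Radiograph, bins: int = 256) -> Radiograph:
    """Global histogram equalization.

    Each pixel maps to the normalized cumulative histogram evaluated at its
    bin, so output values lie in (0, 1] and the mapping is monotone
    non-decreasing. A constant image maps to constant 1.0 (its single bin
    carries all mass).
    """
    if bins < 2:
        raise ParameterError(f"bins must be >= 2, got {bins}")
    px = img.pixels
    hist, _ = np.histogram(px, bins=bins, range=(0.0, 1.0))
    cdf = np.cumsum(hist) / px.size
    idx = np.minimum((px * bins).astype(np.int64), bins - 1)
    return img.with_pixels(cdf[idx])


def apply_ahe(img: Radiograph, tiles: tuple[int, int] = (8, 8),
              clip_limit: float = 0.01) -> Radiograph:
    """Contrast-limited adaptive histogram equalization (CLAHE).

    The image is divided into ``tiles = (rows, cols)`` regions; each
    region's histogram is clipped at ``clip_limit`` (fraction of the
    region's pixel count), the excess redistributed, and per-pixel output
    bilinearly interpolated between neighboring tile mappings.
    """
    tr, tc = tiles
    if tr < 1 or tc < 1:
        raise ParameterError(f"tile grid must be >= (1, 1), got {tiles}")
    if not (0 < clip_limit <= 1):
        raise ParameterError(f"clip_limit must be in (0, 1], got {clip_limit}")
    if tr > img.height or tc > img.width:
        raise ParameterError(
            f"tile grid {tiles} larger than image {img.height}x{img.width}")
    if img.pixels.max() == img.pixels.min():
        return img.with_pixels(img.pixels.copy())  # no contrast to amplify
    kernel = (max(1, img.height // tr), max(1, img.width // tc))
    out = equalize_adapthist(img.pixels, kernel_size=kernel, clip_limit=clip_limit)
    return img.with_pixels(np.clip(out, 0.0, 1.0))


@dataclass(frozen=True)
class EnhancementSpec:
    """An ordered chain of operators with their parameters."""

    ops: tuple[str, ...] = ()
    iam_low_pct: float = 1.0
    iam_high_pct: float = 99.0
    iam_gamma: float = 1.0
    histeq_bins: int = 256
    ahe_tiles: tuple[int, int] = (8, 8)
    ahe_clip_limit: float = 0.01

    def __post_init__(self) -> None:
        object.__setattr__(self, "ops", tuple(op.lower() for op in self.ops))
        if len(self.ops) > 3:
            raise ParameterError(f"at most 3 operators per chain, got {len(self.ops)}")
        for op in self.ops:
            if op not in ("iam", "histeq", "ahe"):
                raise ParameterError(f"unknown operator {op!r}; expected iam, histeq or ahe")


#: Preset chains of the enhancement ablation design, by name.
PRESETS: dict[str, tuple[str, ...]] = {
    "original": (),
    "ahe": ("ahe",),
    "histeq": ("histeq",),
    "iam": ("iam",),
    "histeq+ahe": ("histeq", "ahe"),
    "ahe+iam": ("ahe", "iam"),
    "iam+histeq": ("iam", "histeq"),
    "iam+histeq+ahe": ("iam", "histeq", "ahe"),
}


def preset(name: str) -> EnhancementSpec:
    """Look up a named preset chain."""
    key = name.lower()
    if key not in PRESETS:
        raise ParameterError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    return EnhancementSpec(ops=PRESETS[key])


def apply_chain(img: Radiograph, spec: EnhancementSpec) -> Radiograph:
    """Apply a chain's operators strictly in listed order (empty = identity)."""
    out = img.with_pixels(img.pixels.copy())
    for op in spec.ops:
        if op == "iam":
            out = apply_iam(out, spec.iam_low_pct, spec.iam_high_pct, spec.iam_gamma)
        elif op == "histeq":
            out = apply_histeq(out, spec.histeq_bins)
        elif op == "ahe":
            out = apply_ahe(out, spec.ahe_tiles, spec.ahe_clip_limit)
        else:  # pragma: no cover - spec validation rejects this
            raise ParameterError(f"unknown operator {op!r}")
    return out
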