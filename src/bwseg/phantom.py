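"""Synthetic bitewing phantom with exact ground truth.

The phantom emulates the structures the segmentation pipeline relies on: a
dark background, two horizontal rows of bright tooth blobs separated by a
dark occlusal band, dark interdental gaps, optional bright "restoration"
caps and small dark proximal "caries" notches, additive Gaussian noise,
and a global rotation. Tooth crowns carry rounded cusp bulges that extend
into the occlusal band, so the band's clear height varies tooth by tooth —
as in a real bitewing, only a well-leveled image exposes a fully clear
occlusal row, which keeps the rotation search's optimum sharp.

All randomness flows from the single integer seed in the spec through one
generator instance; the same spec is bit-identical across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import rotation
from .core import Box, ParameterError, Radiograph


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic bitewing. Distances in pixels."""

    width: int = 600
    height: int = 400
    n_upper: int = 4
    n_lower: int = 4
    rotation_deg: float = 0.0  # global rotation g, degrees CCW
    occlusal_gap: int = 30
    interdental_gap: int = 8
    tooth_intensity_mean: float = 0.75
    tooth_intensity_sd: float = 0.05
    background_intensity: float = 0.10
    noise_sd: float = 0.02
    p_restoration: float = 0.3
    p_caries: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_upper < 1 or self.n_lower < 1:
            raise ParameterError("each jaw needs at least one tooth")
        if not (-12.0 <= self.rotation_deg <= 12.0):
            raise ParameterError(f"rotation_deg must be within +-12, got {self.rotation_deg}")
        for name in ("p_restoration", "p_caries"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ParameterError(f"{name} must be in [0, 1], got {p}")
        if self.noise_sd < 0 or self.tooth_intensity_sd < 0:
            raise ParameterError("noise_sd and tooth_intensity_sd must be >= 0")


@dataclass(frozen=True)
class ToothFlags:
    restoration: bool
    caries: bool


@dataclass
class PhantomTruth:
    """Exact ground truth in the canonical (unrotated) frame."""

    rotation_deg: float
    jaw_split_y: int
    upper_boxes: list[Box]
    lower_boxes: list[Box]
    upper_flags: list[ToothFlags]
    lower_flags: list[ToothFlags]

    def boxes(self, jaw: Optional[str] = None) -> list[Box]:
        if jaw == "upper":
            return list(self.upper_boxes)
        if jaw == "lower":
            return list(self.lower_boxes)
        return list(self.upper_boxes) + list(self.lower_boxes)


def generate_phantom(spec: PhantomSpec = PhantomSpec()) -> tuple[Radiograph, PhantomTruth]:
    """Draw the canonical phantom, add noise, rotate by the spec's angle.

    Returns the rotated radiograph and the canonical-frame truth.
    """
    w, h = spec.width, spec.height
    margin_x = round(0.06 * w)
    margin_y = round(0.12 * h)
    js = h // 2
    gap_half = spec.occlusal_gap // 2
    band_top, band_bot = js - gap_half, js + gap_half

    upper_rows = (margin_y, band_top)
    lower_rows = (band_bot, h - margin_y)
    for name, (r0, r1) in (("upper", upper_rows), ("lower", lower_rows)):
        if r1 - r0 < 20:
            raise ParameterError(f"{name} tooth row has only {r1 - r0} rows; canvas too small")

    rng = np.random.default_rng(spec.seed)
    canvas = np.full((h, w), spec.background_intensity, dtype=np.float64)

    def draw_jaw(n_teeth: int, rows: tuple[int, int], jaw: str):
        usable = w - 2 * margin_x - (n_teeth - 1) * spec.interdental_gap
        tooth_w = usable // n_teeth
        if tooth_w < 12:
            raise ParameterError(
                f"{n_teeth} teeth of width {tooth_w} px do not fit a {w} px canvas")
        x = margin_x + (usable - tooth_w * n_teeth) // 2
        boxes, flags = [], []
        # cusp tips reach 33-43% of the occlusal gap from each side, so the
        # fully clear band is 14-34% of the gap: narrow enough that only a
        # well-leveled image exposes an all-background row
        ext_lo = max(1, round(0.33 * spec.occlusal_gap))
        ext_hi = max(ext_lo, round(0.43 * spec.occlusal_gap))
        for _ in range(n_teeth):
            intensity = float(np.clip(
                rng.normal(spec.tooth_intensity_mean, spec.tooth_intensity_sd), 0.3, 1.0))
            ext = int(rng.integers(ext_lo, ext_hi + 1))
            restored = bool(rng.random() < spec.p_restoration)
            carious = bool(rng.random() < spec.p_caries)
            caries_side = "left" if rng.random() < 0.5 else "right"
            box = _draw_tooth(canvas, x, x + tooth_w, rows, jaw, intensity, ext,
                              restored, carious, caries_side)
            boxes.append(box)
            flags.append(ToothFlags(restoration=restored, caries=carious))
            x += tooth_w + spec.interdental_gap
        return boxes, flags

    upper_boxes, upper_flags = draw_jaw(spec.n_upper, upper_rows, "upper")
    lower_boxes, lower_flags = draw_jaw(spec.n_lower, lower_rows, "lower")

    if spec.noise_sd > 0:
        canvas = np.clip(canvas + rng.normal(0.0, spec.noise_sd, canvas.shape), 0.0, 1.0)

    image = Radiograph(canvas, source_bit_depth=0, id=f"phantom-seed{spec.seed}")
    if spec.rotation_deg != 0:
        image = rotation.rotate(image, spec.rotation_deg)
    truth = PhantomTruth(
        rotation_deg=spec.rotation_deg,
        jaw_split_y=js,
        upper_boxes=upper_boxes,
        lower_boxes=lower_boxes,
        upper_flags=upper_flags,
        lower_flags=lower_flags,
    )
    return image, truth


def _draw_tooth(canvas, x0, x1, rows, jaw, intensity, ext,
                restored, carious, caries_side) -> Box:
    """Draw one crown into the canvas, return its exact bounding box."""
    r0, r1 = rows
    tooth_w = x1 - x0
    cols = np.arange(x0, x1)
    u = (cols - x0 + 0.5) / tooth_w
    bulge = np.rint(ext * np.sin(np.pi * u)).astype(int)  # rounded cusp profile
    if jaw == "upper":
        # body spans [r0, r1), cusp extends downward into the occlusal band
        bottoms = r1 + bulge
        for c, b in zip(cols, bottoms):
            canvas[r0:b, c] = intensity
        occlusal_edge = r1
        y_min, y_max = r0, int(bottoms.max())
    else:
        tops = r0 - bulge
        for c, t in zip(cols, tops):
            canvas[t:r1, c] = intensity
        occlusal_edge = r0
        y_min, y_max = int(tops.min()), r1

    cap_h = 12
    if restored:
        cx0, cx1 = x0 + 4, x1 - 4
        if jaw == "upper":
            canvas[occlusal_edge - cap_h:occlusal_edge, cx0:cx1] = 0.95
        else:
            canvas[occlusal_edge:occlusal_edge + cap_h, cx0:cx1] = 0.95
    if carious:
        cx = x0 + 2 if caries_side == "left" else x1 - 3
        cy = occlusal_edge - 10 if jaw == "upper" else occlusal_edge + 10
        yy, xx = np.ogrid[:canvas.shape[0], :canvas.shape[1]]
        notch = ((xx - cx) / 5.0) ** 2 + ((yy - cy) / 7.0) ** 2 <= 1.0
        inside = np.zeros_like(notch)
        inside[min(y_min, cy - 8):max(y_max, cy + 8), x0:x1] = True
        canvas[notch & inside] = 0.15
    return Box(x0, y_min, x1, y_max)


def truth_to_detection_format(truth: PhantomTruth, image_id: str = "phantom") -> dict:
    """Render ground truth in the segmentation sidecar schema."""
    segments = []
    for jaw, boxes in (("upper", truth.upper_boxes), ("lower", truth.lower_boxes)):
        for i, box in enumerate(boxes):
            segments.append({"jaw": jaw, "index": i, "half": "whole",
                             "box": list(box.as_tuple())})
    return {
        "image_id": image_id,
        "rotation_deg": truth.rotation_deg,
        "jaw_split_y": truth.jaw_split_y,
        "segments": segments,
    }
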