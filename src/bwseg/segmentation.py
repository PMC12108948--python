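"""Splitting an angle-corrected bitewing into jaws, teeth, and half-teeth.

After the rotation search has leveled the occlusal band, the image is cut
horizontally at the trough row into upper and lower jaws. Within each jaw,
interdental gaps show up as valleys of the vertical projection profile
(foreground count per column); with n teeth in a row, the n-1 deepest
valleys are the separator columns, and vertical cuts there isolate single
teeth. Each tooth can finally be split at its box midline into left and
right halves — interproximal surfaces, where secondary caries concentrates,
then sit at a patch border.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.signal import find_peaks

from . import preprocessing, rotation
from .core import BinaryImage, Box, DetectionError, ParameterError, Radiograph
from .rotation import ProjectionProfile, RotationSearchResult


@dataclass(frozen=True)
class ToothSegment:
    """One (half-)tooth crop with its provenance.

    ``box`` is expressed in the rotated (angle-corrected) frame of the full
    bitewing; ``index`` counts teeth left-to-right from 0 within a jaw.
    """

    jaw: str  # "upper" | "lower"
    index: int
    half: str  # "left" | "right" | "whole"
    box: Box
    crop: Radiograph

    def __post_init__(self) -> None:
        if self.jaw not in ("upper", "lower"):
            raise ParameterError(f"jaw must be 'upper' or 'lower', got {self.jaw!r}")
        if self.half not in ("left", "right", "whole"):
            raise ParameterError(f"half must be 'left', 'right' or 'whole', got {self.half!r}")
        if (self.crop.height, self.crop.width) != (self.box.height, self.box.width):
            raise ParameterError("crop dimensions must equal box dimensions")


@dataclass
class SegmentationResult:
    image_id: str
    rotation_deg: int
    jaw_split_y: int
    upper_separators: list[int]
    lower_separators: list[int]
    segments: list[ToothSegment]
    angle_table: Optional[rotation.AngleTroughTable] = None

    def whole_teeth(self, jaw: Optional[str] = None) -> list[ToothSegment]:
        return [s for s in self.segments
                if s.half == "whole" and (jaw is None or s.jaw == jaw)]

    def to_dict(self) -> dict:
        return {
            "image_id": self.image_id,
            "rotation_deg": self.rotation_deg,
            "jaw_split_y": self.jaw_split_y,
            "upper_separators": list(map(int, self.upper_separators)),
            "lower_separators": list(map(int, self.lower_separators)),
            "segments": [
                {"jaw": s.jaw, "index": s.index, "half": s.half,
                 "box": list(s.box.as_tuple())}
                for s in self.segments
            ],
        }


@dataclass(frozen=True)
class PipelineConfig:
    """All tunables of the end-to-end segmentation pipeline."""

    sigma: float = 1.5
    erode_h: Optional[int] = None  # None -> width-scaled default
    erode_v: Optional[int] = None  # None -> row-height-scaled default
    coarse_range: int = 15
    coarse_step: int = 5
    fine_step: int = 1
    fine_halfwidth: int = 4
    min_prominence_frac: float = 0.10
    min_separation: Optional[int] = None  # None -> width / 16 (<= 8 teeth/row)
    expected_upper: Optional[int] = None
    expected_lower: Optional[int] = None
    halves: bool = False
    trim: bool = True


# ---------------------------------------------------------------------------
# Stage operations
# ---------------------------------------------------------------------------


def split_jaws(img: Radiograph, jaw_split_y: int) -> tuple[Radiograph, Radiograph]:
    """Cut at a row: upper = rows [0, y), lower = rows [y, H)."""
    if not (0 < jaw_split_y < img.height):
        raise ParameterError(
            f"jaw split row {jaw_split_y} outside (0, {img.height})")
    upper = img.with_pixels(img.pixels[:jaw_split_y].copy())
    lower = img.with_pixels(img.pixels[jaw_split_y:].copy())
    return upper, lower


def vertical_projection(mask: BinaryImage) -> ProjectionProfile:
    """Foreground count per column, full valid range."""
    values = mask.mask.sum(axis=0, dtype=np.int64)
    return ProjectionProfile("column", values, (0, mask.width))


def find_tooth_gaps(
    profile: ProjectionProfile,
    expected_teeth: Optional[int] = None,
    min_separation: int = 10,
    min_prominence_frac: float = 0.10,
) -> list[int]:
    """Separator columns at interdental valleys of a vertical profile.

    Candidates are local minima (plateau centers for flat valleys) with
    prominence at least ``min_prominence_frac * max(profile)`` and pairwise
    distance at least ``min_separation``. When ``expected_teeth = n`` is
    given, the n-1 most prominent candidates are returned (deeper valley
    wins ties); otherwise all candidates. Sorted ascending.
    """
    if profile.axis != "column":
        raise ParameterError("find_tooth_gaps expects a column (vertical) profile")
    values = profile.values.astype(np.float64)
    vmax = values.max()
    candidates: list[int] = []
    prominences: list[float] = []
    if vmax > 0:
        inverted = vmax - values
        peaks, props = find_peaks(
            inverted,
            prominence=min_prominence_frac * vmax,
            distance=max(1, int(min_separation)),
            plateau_size=(1, None),
        )
        # flat valleys are reported by their plateau edges; use the center
        candidates = [int((l + r) // 2)
                      for l, r in zip(props["left_edges"], props["right_edges"])]
        prominences = list(props["prominences"])
    if expected_teeth is None:
        return sorted(candidates)
    needed = expected_teeth - 1
    if needed < 0:
        raise ParameterError(f"expected_teeth must be >= 1, got {expected_teeth}")
    if len(candidates) < needed:
        raise DetectionError(
            f"expected {expected_teeth} teeth (need {needed} separators) but only "
            f"{len(candidates)} qualifying valleys found "
            f"(prominence >= {min_prominence_frac:.2f} x max, "
            f"separation >= {min_separation} px)")
    ranked = sorted(zip(prominences, candidates), key=lambda pc: (-pc[0], pc[1]))
    return sorted(c for _, c in ranked[:needed])


def segment_teeth(
    row_img: Radiograph,
    separators: Sequence[int],
    jaw: str = "upper",
    trim: bool = True,
) -> list[ToothSegment]:
    """Cut a jaw row at separator columns into whole-tooth segments.

    k separators tile the row into k+1 segments. With ``trim``, each crop
    is clipped vertically to the foreground extent of its column span
    (spans with no foreground are kept untrimmed). Boxes are relative to
    ``row_img``.
    """
    seps = [int(s) for s in separators]
    if seps != sorted(set(seps)):
        raise ParameterError(f"separators must be strictly increasing, got {separators}")
    if seps and not (0 < seps[0] and seps[-1] < row_img.width):
        raise ParameterError(f"separators {separators} outside (0, {row_img.width})")
    bounds = [0] + seps + [row_img.width]
    mask = preprocessing.binarize(row_img).mask if trim else None
    segments = []
    for i, (x0, x1) in enumerate(zip(bounds[:-1], bounds[1:])):
        y0, y1 = 0, row_img.height
        if mask is not None:
            rows = np.flatnonzero(mask[:, x0:x1].any(axis=1))
            if rows.size:
                y0, y1 = int(rows[0]), int(rows[-1]) + 1
        box = Box(x0, y0, x1, y1)
        crop = row_img.with_pixels(row_img.pixels[y0:y1, x0:x1].copy())
        segments.append(ToothSegment(jaw, i, "whole", box, crop))
    return segments


def split_halves(segment: ToothSegment) -> tuple[ToothSegment, ToothSegment]:
    """Split a whole tooth at its box midline into left and right halves.

    For odd widths the extra column goes to the right half.
    """
    if segment.half != "whole":
        raise ParameterError("can only split a whole-tooth segment")
    if segment.box.width < 2:
        raise ParameterError(f"box width {segment.box.width} < 2 cannot be split")
    mid = segment.box.x0 + segment.box.width // 2
    w_left = mid - segment.box.x0
    left = replace(
        segment, half="left",
        box=Box(segment.box.x0, segment.box.y0, mid, segment.box.y1),
        crop=segment.crop.with_pixels(segment.crop.pixels[:, :w_left].copy()))
    right = replace(
        segment, half="right",
        box=Box(mid, segment.box.y0, segment.box.x1, segment.box.y1),
        crop=segment.crop.with_pixels(segment.crop.pixels[:, w_left:].copy()))
    return left, right


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------


def segment_bitewing(img: Radiograph, config: PipelineConfig = PipelineConfig()) -> SegmentationResult:
    """Full pipeline: angle search, jaw split, per-jaw tooth segmentation.

    Boxes are reported in the angle-corrected frame; ``rotation_deg``
    records the correction applied so they can be mapped back with
    :func:`box_to_original_frame`.
    """
    search = rotation.coarse_to_fine_search(
        img,
        coarse_range=config.coarse_range,
        coarse_step=config.coarse_step,
        fine_step=config.fine_step,
        fine_halfwidth=config.fine_halfwidth,
        sigma=config.sigma,
        erode_h=config.erode_h,
    )
    corrected = rotation.rotate(img, search.best_angle)
    if search.trough_y is None or not (0 < search.trough_y < corrected.height):
        raise DetectionError(
            f"rotation search produced no usable jaw-split row ({search.trough_y})")
    upper, lower = split_jaws(corrected, search.trough_y)

    segments: list[ToothSegment] = []
    separators: dict[str, list[int]] = {}
    for jaw, row_img, expected, y_offset in (
        ("upper", upper, config.expected_upper, 0),
        ("lower", lower, config.expected_lower, search.trough_y),
    ):
        try:
            seps = _jaw_separators(row_img, expected, config)
            whole = segment_teeth(row_img, seps, jaw=jaw, trim=config.trim)
        except (DetectionError, ParameterError) as exc:
            raise DetectionError(f"{jaw} jaw: {exc}") from exc
        separators[jaw] = seps
        for seg in whole:
            seg = _offset_segment(seg, y_offset)
            segments.append(seg)
            if config.halves:
                segments.extend(split_halves(seg))

    return SegmentationResult(
        image_id=img.id,
        rotation_deg=search.best_angle,
        jaw_split_y=search.trough_y,
        upper_separators=separators["upper"],
        lower_separators=separators["lower"],
        segments=segments,
        angle_table=search.table,
    )


def _jaw_separators(row_img: Radiograph, expected: Optional[int],
                    config: PipelineConfig) -> list[int]:
    smoothed = preprocessing.gaussian_smooth(row_img, config.sigma)
    mask = preprocessing.binarize(smoothed)
    length = (config.erode_v if config.erode_v is not None
              else preprocessing.default_erode_v(row_img.height))
    eroded = preprocessing.erode(mask, "vertical", length)
    profile = vertical_projection(eroded)
    min_sep = (config.min_separation if config.min_separation is not None
               else max(1, row_img.width // 16))
    return find_tooth_gaps(
        profile,
        expected_teeth=expected,
        min_separation=min_sep,
        min_prominence_frac=config.min_prominence_frac,
    )


def _offset_segment(seg: ToothSegment, y_offset: int) -> ToothSegment:
    if y_offset == 0:
        return seg
    b = seg.box
    return replace(seg, box=Box(b.x0, b.y0 + y_offset, b.x1, b.y1 + y_offset))


def box_to_original_frame(box: Box, rotation_deg: float,
                          height: int, width: int) -> tuple[tuple[float, float], ...]:
    """Map a box's corners from the angle-corrected frame back to the input.

    The correction rotated the image by ``rotation_deg`` counterclockwise
    about the canvas center; the inverse maps corrected-frame coordinates
    back. Returns the four (x, y) corner coordinates (floats) in the
    original frame, in order (x0,y0), (x1,y0), (x1,y1), (x0,y1).
    """
    theta = np.deg2rad(rotation_deg)
    cx, cy = (width - 1) / 2.0, (height - 1) / 2.0
    # image-frame CCW rotation corresponds to this matrix with y down
    c, s = np.cos(theta), np.sin(theta)
    corners = [(box.x0, box.y0), (box.x1, box.y0), (box.x1, box.y1), (box.x0, box.y1)]
    out = []
    for x, y in corners:
        dx, dy = x - cx, y - cy
        out.append((cx + c * dx - s * dy, cy + s * dx + c * dy))
    return tuple(out)
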