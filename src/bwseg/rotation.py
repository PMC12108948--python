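"""Coarse-to-fine search for the bitewing's optimal rotation angle.

A bitewing's two tooth rows are separated by the dark occlusal band. When
the image is rotated so that this band runs exactly horizontally, some row
of the binarized image crosses only background, and the horizontal
projection profile (foreground count per row) dips to its global minimum —
the *trough*. The search therefore rotates the image over a grid of
angles, binarizes each, projects the middle third of rows (masking the two
outer thirds, which contain the tooth crowns and roots), and keeps the
angle whose trough is lowest. A coarse 5-degree pass brackets the optimum
and a fine 1-degree pass around the coarse winner refines it; only integer
angles are evaluated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from skimage.transform import rotate as _sk_rotate

from . import preprocessing
from .core import BinaryImage, ParameterError, Radiograph


@dataclass(frozen=True)
class ProjectionProfile:
    """Per-row or per-column foreground counts of a binary image.

    ``values[i]`` is the exact number of foreground pixels in row/column
    ``i``; ``valid_range`` is the half-open index interval the trough
    search is allowed to inspect (after masking).
    """

    axis: str  # "row" | "column"
    values: np.ndarray
    valid_range: tuple[int, int]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.int64)
        if self.axis not in ("row", "column"):
            raise ParameterError(f"axis must be 'row' or 'column', got {self.axis!r}")
        if (v < 0).any():
            raise ParameterError("projection values must be non-negative")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class TroughEntry:
    """Trough value (masked-profile minimum) and its row for one angle."""

    value: int
    row: Optional[int] = None


@dataclass
class AngleTroughTable:
    """Map from integer angle (degrees) to its trough entry."""

    entries: dict[int, TroughEntry] = field(default_factory=dict)

    def add(self, angle: int, value: int, row: Optional[int] = None) -> None:
        self.entries[int(angle)] = TroughEntry(int(value), row)

    def angles(self) -> list[int]:
        return sorted(self.entries)

    def __contains__(self, angle: int) -> bool:
        return int(angle) in self.entries

    def __getitem__(self, angle: int) -> TroughEntry:
        return self.entries[int(angle)]


@dataclass(frozen=True)
class RotationSearchResult:
    """Outcome of the two-stage angle search."""

    best_angle: int
    trough_value: int
    trough_y: Optional[int]
    table: AngleTroughTable


# ---------------------------------------------------------------------------
# Primitive operations
# ---------------------------------------------------------------------------


def rotate(img: Radiograph, angle: float) -> Radiograph:
    """Rotate about the image center, counterclockwise for positive angles.

    Bilinear interpolation; the canvas size is preserved and exposed
    corners are filled with 0 (background air). ``angle = 0`` is an exact
    identity.
    """
    if not np.isfinite(angle):
        raise ParameterError(f"angle must be finite, got {angle}")
    if angle == 0:
        return img.with_pixels(img.pixels.copy())
    out = _sk_rotate(img.pixels, angle, resize=False, order=1, mode="constant",
                     cval=0.0, preserve_range=True)
    return img.with_pixels(np.clip(out, 0.0, 1.0))


def horizontal_projection(mask: BinaryImage, middle_only: bool = False) -> ProjectionProfile:
    """Foreground count per row; optionally restrict search to the middle third.

    With ``middle_only`` the valid range is rows ``[H//3, 2*H//3)``,
    masking the upper and lower thirds so the trough search focuses on the
    occlusal band between the jaws.
    """
    values = mask.mask.sum(axis=1, dtype=np.int64)
    h = mask.height
    valid = (h // 3, 2 * h // 3) if middle_only else (0, h)
    return ProjectionProfile("row", values, valid)


def trough(profile: ProjectionProfile) -> tuple[int, int]:
    """Minimum value within the profile's valid range and its index.

    Ties are broken by the smallest index.
    """
    lo, hi = profile.valid_range
    if hi <= lo:
        raise ParameterError(f"empty valid range {profile.valid_range}")
    window = profile.values[lo:hi]
    pos = int(np.argmin(window)) + lo
    return int(profile.values[pos]), pos


def evaluate_angle(
    img: Radiograph,
    angle: float,
    sigma: float = 1.5,
    erode_h: Optional[int] = None,
) -> tuple[int, int]:
    """Trough value and trough row of the image rotated by ``angle``.

    Pipeline: rotate -> Gaussian smooth -> Otsu binarize -> horizontal
    erosion -> middle-masked horizontal projection -> trough.
    """
    rotated = rotate(img, angle)
    smoothed = preprocessing.gaussian_smooth(rotated, sigma)
    mask = preprocessing.binarize(smoothed)
    length = erode_h if erode_h is not None else preprocessing.default_erode_h(img.width)
    eroded = preprocessing.erode(mask, "horizontal", length)
    profile = horizontal_projection(eroded, middle_only=True)
    return trough(profile)


# ---------------------------------------------------------------------------
# Two-stage search
# ---------------------------------------------------------------------------

_TIE_KEY = lambda angle_value: (angle_value[1], abs(angle_value[0]), angle_value[0])  # noqa: E731


def coarse_to_fine_search(
    img: Radiograph,
    coarse_range: int = 15,
    coarse_step: int = 5,
    fine_step: int = 1,
    fine_halfwidth: int = 4,
    sigma: float = 1.5,
    erode_h: Optional[int] = None,
) -> RotationSearchResult:
    """Two-stage argmin search over integer rotation angles.

    Stage 1 evaluates ``{-R, -R+step, ..., +R}``; stage 2 evaluates
    ``fine_step`` increments within ``+-fine_halfwidth`` of the stage-1
    winner (reusing already-evaluated angles rather than recomputing them).
    The overall winner is the argmin over stage-2 candidates plus the
    stage-1 best; ties go to the smaller ``|angle|``, then the smaller
    signed angle.
    """
    if not (coarse_step > fine_step > 0):
        raise ParameterError(
            f"need coarse_step > fine_step > 0, got {coarse_step}, {fine_step}")
    table = AngleTroughTable()

    def measure(angle: int) -> int:
        if angle not in table:
            value, row = evaluate_angle(img, angle, sigma=sigma, erode_h=erode_h)
            table.add(angle, value, row)
        return table[angle].value

    coarse_angles = list(range(-coarse_range, coarse_range + 1, coarse_step))
    coarse_best = min(coarse_angles, key=lambda a: _TIE_KEY((a, measure(a))))

    fine_angles = [coarse_best] + [
        a for a in range(coarse_best - fine_halfwidth, coarse_best + fine_halfwidth + 1, fine_step)
        if a != coarse_best
    ]
    best = min(fine_angles, key=lambda a: _TIE_KEY((a, measure(a))))
    entry = table[best]
    return RotationSearchResult(best, entry.value, entry.row, table)


def select_angle_from_table(
    table: AngleTroughTable,
    coarse_step: int = 5,
    fine_halfwidth: int = 4,
    coarse_range: int = 15,
) -> tuple[int, int, int]:
    """Run the two-stage selection on a pre-computed angle-to-trough table.

    Stage 1 considers entries whose angle is a multiple of ``coarse_step``
    within ``+-coarse_range``; stage 2 considers entries within
    ``+-fine_halfwidth`` of the stage-1 winner (plus the winner itself).
    Angles absent from the table are skipped. Returns
    ``(coarse_best, final_best, final_value)``.
    """
    if not table.entries:
        raise ParameterError("empty angle-trough table")
    coarse = [a for a in table.angles()
              if a % coarse_step == 0 and abs(a) <= coarse_range]
    if not coarse:
        raise ParameterError(f"table contains no multiple of {coarse_step} within +-{coarse_range}")
    coarse_best = min(coarse, key=lambda a: _TIE_KEY((a, table[a].value)))
    fine = [a for a in table.angles() if abs(a - coarse_best) <= fine_halfwidth]
    final_best = min(set(fine) | {coarse_best},
                     key=lambda a: _TIE_KEY((a, table[a].value)))
    return coarse_best, final_best, table[final_best].value
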