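"""Shared domain types, intensity normalization, and image / sidecar I/O.

Conventions used throughout the package:

* images are 2-D ``float64`` arrays of intensities in ``[0, 1]``, indexed
  ``(row y, column x)`` with y increasing downward;
* bounding boxes are 0-based, half-open: ``[x0, x1) x [y0, y1)``;
* binary masks hold exactly 0 (background: gaps, air) and 1 (foreground:
  bright tooth / restoration material).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import imageio.v3 as iio
import numpy as np


class BWSegError(Exception):
    """Base class for all errors raised by this package."""


class InputError(BWSegError):
    """An input file or image is missing, unreadable, or malformed."""


class ParameterError(BWSegError, ValueError):
    """A parameter is outside its documented range."""


class DetectionError(BWSegError):
    """A detection stage could not produce the requested structure."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Radiograph:
    """A 2-D grayscale radiograph with intensities normalized to [0, 1].

    Parameters
    ----------
    pixels
        2-D float array, values in ``[0, 1]``, indexed ``(y, x)``.
    source_bit_depth
        Bit depth of the file the image came from: 8, 16, or 0 for
        float-valued in-memory images.
    id
        Free-text provenance label (file stem, phantom seed, ...).
    """

    pixels: np.ndarray
    source_bit_depth: int = 0
    id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise InputError(f"radiograph must be a non-empty 2-D grid, got shape {px.shape}")
        if not np.all(np.isfinite(px)):
            raise InputError("radiograph intensities must be finite")
        if px.min() < 0.0 or px.max() > 1.0:
            raise InputError("radiograph intensities must lie in [0, 1]")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    def with_pixels(self, pixels: np.ndarray) -> "Radiograph":
        """A copy of this radiograph carrying new pixel data."""
        return Radiograph(pixels, source_bit_depth=self.source_bit_depth, id=self.id)


@dataclass(frozen=True)
class BinaryImage:
    """A {0, 1} mask sharing the indexing of its source radiograph."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.mask)
        if m.ndim != 2 or m.size == 0:
            raise InputError(f"mask must be a non-empty 2-D grid, got shape {m.shape}")
        if not np.isin(m, (0, 1)).all():
            raise InputError("mask values must be exactly 0 or 1")
        object.__setattr__(self, "mask", m.astype(np.uint8))

    @property
    def height(self) -> int:
        return self.mask.shape[0]

    @property
    def width(self) -> int:
        return self.mask.shape[1]


@dataclass(frozen=True)
class Box:
    """Half-open axis-aligned pixel box ``[x0, x1) x [y0, y1)``."""

    x0: int
    y0: int
    x1: int
    y1: int

    def __post_init__(self) -> None:
        for name in ("x0", "y0", "x1", "y1"):
            v = getattr(self, name)
            if int(v) != v:
                raise ParameterError(f"box coordinate {name}={v} is not an integer")
            object.__setattr__(self, name, int(v))
        if not (self.x0 < self.x1 and self.y0 < self.y1):
            raise ParameterError(f"degenerate box {self.as_tuple()}: need x0 < x1 and y0 < y1")

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.x0, self.y0, self.x1, self.y1)

    @property
    def width(self) -> int:
        return self.x1 - self.x0

    @property
    def height(self) -> int:
        return self.y1 - self.y0

    @property
    def area(self) -> int:
        return self.width * self.height


PathLike = Union[str, Path]


# ---------------------------------------------------------------------------
# Image I/O
# ---------------------------------------------------------------------------


def read_radiograph(path: PathLike) -> Radiograph:
    """Read an 8/16-bit PNG/TIFF/JPEG (or single-frame monochrome DICOM).

    RGB(A) files are converted to grayscale by the mean of the first three
    channels; intensities are rescaled to ``[0, 1]`` by the bit-depth
    maximum, which preserves pixel ordering.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    if path.suffix.lower() in {".dcm", ".dicom"}:
        arr, bit_depth = _read_dicom(path)
    else:
        try:
            arr = np.asarray(iio.imread(path))
        except Exception as exc:  # imageio raises various types
            raise InputError(f"could not read image {path}: {exc}") from exc
        if arr.dtype == np.uint8:
            bit_depth = 8
        elif arr.dtype == np.uint16:
            bit_depth = 16
        else:
            bit_depth = 0
        if arr.ndim == 3:
            arr = arr[..., :3].mean(axis=2)
    if arr.ndim != 2 or arr.size == 0:
        raise InputError(f"{path}: expected a non-empty 2-D grayscale image, got shape {arr.shape}")
    arr = arr.astype(np.float64)
    if bit_depth:
        arr = arr / (2**bit_depth - 1)
    else:
        arr = np.clip(arr, 0.0, 1.0)
    return Radiograph(arr, source_bit_depth=bit_depth, id=path.stem)


def _read_dicom(path: Path) -> tuple[np.ndarray, int]:
    try:
        import pydicom
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise InputError("DICOM support requires the optional 'pydicom' dependency") from exc
    ds = pydicom.dcmread(path)
    arr = np.asarray(ds.pixel_array)
    if arr.ndim != 2:
        raise InputError(f"{path}: only single-frame monochrome DICOM is supported")
    bits = int(getattr(ds, "BitsStored", 16))
    return arr.astype(np.float64) / (2**bits - 1), bits


def write_segment(crop: Radiograph, path: PathLike) -> None:
    """Write a crop as a lossless 8-bit PNG (float quantized by rounding)."""
    path = Path(path)
    data = np.rint(crop.pixels * 255.0).astype(np.uint8)
    try:
        iio.imwrite(path, data, extension=".png")
    except Exception as exc:
        raise InputError(f"could not write {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Result sidecar
# ---------------------------------------------------------------------------


def write_result_sidecar(result, path: PathLike) -> None:
    """Write a segmentation result as a JSON sidecar.

    Schema::

        {"image_id": str, "rotation_deg": float, "jaw_split_y": int,
         "segments": [{"jaw": "upper"|"lower", "index": int,
                       "half": "left"|"right"|"whole",
                       "box": [x0, y0, x1, y1]}]}

    ``result`` is any object with a ``to_dict()`` method producing that
    schema (``bwseg.segmentation.SegmentationResult``, phantom truth
    converted by ``truth_to_detection_format`` is already a dict).
    """
    payload = result.to_dict() if hasattr(result, "to_dict") else dict(result)
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_result_sidecar(path: PathLike) -> dict:
    """Read a JSON sidecar back into its dict form (see write_result_sidecar)."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such sidecar: {path}")
    payload = json.loads(path.read_text())
    for key in ("image_id", "rotation_deg", "jaw_split_y", "segments"):
        if key not in payload:
            raise InputError(f"sidecar {path} missing required key {key!r}")
    return payload
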