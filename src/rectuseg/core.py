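"""Shared containers and errors for the rectus-abdominis measurement pipeline.

The pipeline works on calibrated grayscale ultrasound frames.  Every container
carries enough metadata (per-axis pixel size in mm) to convert pixel
measurements into physical distances at any stage.

Conventions used throughout the package:

* grids are 2-D ``numpy`` arrays indexed ``[row, col]``; row 0 is the top of
  the image and columns run laterally (left-right across the abdomen);
* rectangles are 0-based with **inclusive** bounds
  ``(row_min, row_max, col_min, col_max)``;
* pixel sizes are ``(row_mm, col_mm)`` pairs — mm of tissue per pixel along
  each axis.  The lateral (column) pixel size converts the inter-muscle pixel
  gap into a physical distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple

import numpy as np

__all__ = [
    "RectusegError",
    "ParameterError",
    "CalibrationError",
    "DegenerateInputError",
    "ShapeError",
    "DataError",
    "Frame",
    "CropResult",
    "ProbMap",
    "BinaryMask",
    "Measurement",
]


class RectusegError(Exception):
    """Base class for package errors."""


class ParameterError(RectusegError, ValueError):
    """An argument violates its documented precondition."""


class CalibrationError(RectusegError, ValueError):
    """Pixel-size calibration is missing or invalid."""


class DegenerateInputError(RectusegError, ValueError):
    """Input is structurally valid but degenerate for the operation
    (constant image for thresholding, empty mask for a distance, ...)."""


class ShapeError(RectusegError, ValueError):
    """Grids that must share a shape (or satisfy a divisibility rule) do not."""


class DataError(RectusegError, ValueError):
    """A dataset/subset required by the operation is empty or inconsistent."""


def _check_pixel_size(pixel_size_mm: Tuple[float, float]) -> Tuple[float, float]:
    row_mm, col_mm = float(pixel_size_mm[0]), float(pixel_size_mm[1])
    if not (row_mm > 0 and col_mm > 0):
        raise CalibrationError(f"pixel sizes must be positive, got {pixel_size_mm!r}")
    return (row_mm, col_mm)


@dataclass
class Frame:
    """A calibrated grayscale ultrasound frame.

    Parameters
    ----------
    pixels
        2-D ``uint8`` intensity grid.
    pixel_size_mm
        ``(row, col)`` physical pixel size in mm/pixel.
    source_id
        Opaque identifier (file stem, phantom id, ...).
    """

    pixels: np.ndarray
    pixel_size_mm: Tuple[float, float]
    source_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ParameterError("Frame.pixels must be a non-empty 2-D grid")
        if self.pixels.dtype != np.uint8:
            if self.pixels.min() < 0 or self.pixels.max() > 255:
                raise ParameterError("Frame intensities must lie in [0, 255]")
            self.pixels = self.pixels.astype(np.uint8)
        self.pixel_size_mm = _check_pixel_size(self.pixel_size_mm)

    @property
    def shape(self) -> Tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass
class CropResult:
    """A cropped frame plus the inclusive rectangle it came from."""

    cropped: Frame
    box: Tuple[int, int, int, int]  # row_min, row_max, col_min, col_max

    def __post_init__(self) -> None:
        r0, r1, c0, c1 = self.box
        h, w = self.cropped.shape
        if not (0 <= r0 <= r1 and 0 <= c0 <= c1):
            raise ParameterError(f"invalid crop box {self.box!r}")
        if (r1 - r0 + 1, c1 - c0 + 1) != (h, w):
            raise ParameterError("cropped dimensions do not match box dimensions")


@dataclass
class ProbMap:
    """Per-pixel foreground probability on the model grid."""

    values: np.ndarray
    pixel_size_mm: Tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ParameterError("ProbMap.values must be 2-D")
        if self.values.size and (self.values.min() < 0.0 or self.values.max() > 1.0):
            raise ParameterError("probabilities must lie in [0, 1]")
        self.pixel_size_mm = _check_pixel_size(self.pixel_size_mm)


@dataclass
class BinaryMask:
    """A {0,1} segmentation mask on a stated calibrated grid."""

    values: np.ndarray
    pixel_size_mm: Tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        uniq = np.unique(arr)
        if not np.isin(uniq, (0, 1)).all():
            raise ParameterError("mask values must be 0/1")
        if arr.ndim != 2:
            raise ParameterError("BinaryMask.values must be 2-D")
        self.values = arr.astype(np.uint8)
        self.pixel_size_mm = _check_pixel_size(self.pixel_size_mm)

    @property
    def shape(self) -> Tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    def astype_bool(self) -> np.ndarray:
        return self.values.astype(bool)


@dataclass
class Measurement:
    """Result of measuring the inter-muscle gap on one mask.

    ``D_mm = px_mm * d_px`` exactly; ``d_px`` is the count of background
    columns strictly between the two muscle bounding rectangles (0 when the
    muscles form a single region, touch, or overlap laterally).
    """

    d_px: int
    px_mm: float
    D_mm: float
    n_regions: int
    dra_separated: bool
    valid: bool
    dra_threshold_mm: float = field(default=25.0)

    def __post_init__(self) -> None:
        if self.d_px < 0:
            raise ParameterError("d_px must be non-negative")
        if self.px_mm <= 0:
            raise CalibrationError("px_mm must be positive")
        if self.n_regions not in (0, 1, 2):
            raise ParameterError("n_regions must be 0, 1 or 2")
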