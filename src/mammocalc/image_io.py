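"""Image reading/writing, MIAS-style lesion metadata, ROI extraction and
gray normalization.

The internal coordinate convention is 0-based ``(row, col)`` with the origin
at the top-left pixel centre.  MIAS metadata places its origin at the
bottom-left, so the *y* coordinate is converted at the parse boundary and
nowhere else.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np

from .errors import DegenerateInputError, DimensionError, FormatError, ParseError

__all__ = [
    "GrayImage",
    "LesionRecord",
    "read_image",
    "write_image",
    "parse_lesion_metadata",
    "extract_roi",
    "normalize_gray",
]


@dataclass
class GrayImage:
    """A 2-D grayscale image with bit depth and pixel-spacing metadata.

    ``pixels`` stay in whatever numeric type they were produced with;
    normalized images are kept in floating point (quantization to integer
    gray levels happens only inside GLCM/histogram construction).
    """

    pixels: np.ndarray
    bit_depth: int = 8
    spacing_um: float | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise DimensionError(
                f"expected a 2-D image, got shape {self.pixels.shape}")
        if not np.all(np.isfinite(self.pixels.astype(float))):
            raise DegenerateInputError("image contains non-finite pixels")
        if np.any(self.pixels.astype(float) < 0):
            raise DegenerateInputError("image contains negative pixels")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class LesionRecord:
    """One annotated abnormality: centre in (col, row) image coordinates."""

    ref_id: str
    severity: str  # "benign" | "malignant"
    center: tuple[int, int] = field(default=(0, 0))  # (col, row), top-left origin
    radius_px: float = 1.0

    def __post_init__(self) -> None:
        if self.radius_px <= 0:
            raise ParseError(f"radius must be positive, got {self.radius_px}", 0)


def as_pixels(image: "GrayImage | np.ndarray") -> np.ndarray:
    """Return the pixel array of a :class:`GrayImage` or pass arrays through."""
    if isinstance(image, GrayImage):
        return image.pixels
    return np.asarray(image)


def read_image(path: str | Path) -> GrayImage:
    """Read a PGM (P2/P5) or grayscale PNG file.

    Intensities are returned exactly as stored; 16-bit inputs are preserved,
    not rescaled.  Color images are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such image file: {path}")
    try:
        arr = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - normalize reader errors
        raise FormatError(f"could not read image {path}: {exc}") from exc
    if arr.ndim == 3:
        raise FormatError(f"color image not supported: {path}")
    if arr.ndim != 2:
        raise FormatError(f"unsupported image layout {arr.shape}: {path}")
    bit_depth = 16 if arr.dtype.itemsize > 1 else 8
    return GrayImage(arr, bit_depth=bit_depth)


def write_image(image: GrayImage | np.ndarray, path: str | Path) -> None:
    """Write an image as PGM or PNG (decided by extension).

    Floating-point pixels are rounded to the nearest integer level; integer
    pixels round-trip exactly.
    """
    arr = as_pixels(image)
    bit_depth = image.bit_depth if isinstance(image, GrayImage) else 8
    hi = (1 << bit_depth) - 1
    out = np.clip(np.rint(arr), 0, hi)
    out = out.astype(np.uint16 if bit_depth > 8 else np.uint8)
    iio.imwrite(Path(path), out)


def parse_lesion_metadata(text: str, image_height: int = 1024) -> list[LesionRecord]:
    """Parse MIAS-style whitespace-delimited lesion metadata.

    Line layout: ``ref_id tissue class [severity x y radius]``.  Lines
    without coordinates (normal cases, class ``NORM``) yield no record.
    The metadata's bottom-left-origin ``y`` is converted to a top-left row
    index: ``row = image_height - 1 - y``.
    """
    severities = {"B": "benign", "M": "malignant"}
    records: list[LesionRecord] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        tokens = raw.split()
        if not tokens:
            continue
        if len(tokens) < 3:
            raise ParseError(f"expected at least 3 fields, got {len(tokens)}", lineno)
        if len(tokens) == 3:
            continue  # normal case, no lesion coordinates
        if len(tokens) < 7:
            raise ParseError(
                f"abnormal line needs severity,x,y,radius; got {len(tokens)} fields",
                lineno)
        ref_id, severity = tokens[0], tokens[3]
        try:
            x, y, radius = (float(tokens[k]) for k in (4, 5, 6))
        except ValueError as exc:
            raise ParseError(f"malformed numeric field: {exc}", lineno) from exc
        if radius <= 0:
            raise ParseError(f"radius must be positive, got {radius}", lineno)
        row = image_height - 1 - int(y)
        records.append(
            LesionRecord(
                ref_id=ref_id,
                severity=severities.get(severity, severity.lower()),
                center=(int(x), row),
                radius_px=radius,
            ))
    return records


def extract_roi(image: GrayImage | np.ndarray,
                center: tuple[int, int],
                size: int) -> GrayImage:
    """Cut a ``size``-square ROI containing ``center`` (given as (col, row)).

    Windows overlapping the image border are shifted inward rather than
    zero-padded, so texture statistics are never contaminated by padding.
    """
    arr = as_pixels(image)
    rows, cols = arr.shape
    if size < 8:
        raise DimensionError(f"ROI size must be >= 8, got {size}")
    if size > rows or size > cols:
        raise DimensionError(
            f"ROI size {size} exceeds image dimensions {arr.shape}")
    col_c, row_c = center
    r0 = int(np.clip(row_c - size // 2, 0, rows - size))
    c0 = int(np.clip(col_c - size // 2, 0, cols - size))
    block = arr[r0:r0 + size, c0:c0 + size].copy()
    meta = image if isinstance(image, GrayImage) else None
    return GrayImage(block,
                     bit_depth=meta.bit_depth if meta else 8,
                     spacing_um=meta.spacing_um if meta else None)


def normalize_gray(roi: GrayImage | np.ndarray) -> GrayImage:
    """Stretch gray scale linearly to [0, 255].

    ``G1 = (G0 - min) * 255 / (max - min)``.  Output is kept in floating
    point; its minimum is exactly 0 and its maximum exactly 255.
    """
    arr = as_pixels(roi).astype(float)
    lo, hi = float(arr.min()), float(arr.max())
    if hi == lo:
        raise DegenerateInputError(
            "constant image cannot be gray-normalized (zero dynamic range)")
    # divide before scaling so the maximum maps to exactly 255
    out = ((arr - lo) / (hi - lo)) * 255.0
    meta = roi if isinstance(roi, GrayImage) else None
    # the stretched range is 8-bit regardless of the source bit depth
    return GrayImage(out, bit_depth=8,
                     spacing_um=meta.spacing_um if meta else None)
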