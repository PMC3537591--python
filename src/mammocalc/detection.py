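"""Two-branch microcalcification segmentation.

Microcalcifications are small bright deposits, i.e. localized high-frequency
structure on a slowly varying parenchymal background.  The detector combines

* a spatial branch: Laplacian sharpening minus a 3x3 box smoothing produces a
  difference image whose high-frequency content is turned into an edge map by
  the Kirsch compass operator and thresholded;
* a wavelet branch: a 4-level DB4 decomposition with the finest-level details
  and the entire coarsest level zeroed, reconstructed and thresholded, which
  keeps band-pass (levels 2-3) content where calcifications live;

and fuses the two binary masks with a pixel-wise logical AND, so a pixel
must look calcification-like in both domains.  Connected spots are then
labeled and measured (centroid, weighted area, Euler number).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy import ndimage
from skimage.filters import threshold_otsu

from .errors import (
    DegenerateInputError,
    DimensionError,
    EmptyRegionError,
)
from .image_io import as_pixels

__all__ = [
    "DetectionConfig",
    "BinaryMask",
    "Spot",
    "DetectionResult",
    "laplacian_sharpen",
    "smooth3x3",
    "difference_image",
    "kirsch_edges",
    "binarize",
    "wavelet_bandpass",
    "weighted_area",
    "euler_number",
    "detect",
]

_LAPLACIAN_4 = np.array([[0, 1, 0], [1, -4, 1], [0, 1, 0]], dtype=float)
_LAPLACIAN_8 = np.array([[1, 1, 1], [1, -8, 1], [1, 1, 1]], dtype=float)

_EIGHT = np.ones((3, 3), dtype=int)          # 8-connectivity structure
_FOUR = ndimage.generate_binary_structure(2, 1)  # 4-connectivity structure


@dataclass
class DetectionConfig:
    """Tunables of the fused detector.

    Thresholding methods, zeroed DWT layers and the minimum spot size are
    all exposed here; defaults follow the package's methods note.
    """

    edge_percentile: float = 97.0       # spatial-branch threshold percentile
    wavelet_method: str = "percentile"  # wavelet-branch binarization
    wavelet_percentile: float = 98.5    # used when wavelet_method="percentile"
    dwt_wavelet: str = "db4"
    dwt_levels: int = 4
    zero_levels: tuple[int, ...] = (1, 4)   # detail layers set to zero
    zero_approx: bool = True                # also zero the coarsest approximation
    min_spot_px: int = 2
    eight_neighbor_laplacian: bool = False


@dataclass
class BinaryMask:
    """A {0,1} mask with 8-connected foreground convention."""

    pixels: np.ndarray
    connectivity: int = 8

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if not np.isin(arr, (0, 1)).all():
            raise DegenerateInputError("mask values must be strictly binary")
        self.pixels = arr.astype(np.uint8)

    def __array__(self, dtype=None, copy=None):
        return self.pixels.astype(dtype) if dtype else self.pixels


@dataclass
class Spot:
    """One detected spot (8-connected component of the fused mask)."""

    centroid: tuple[float, float]   # (row, col)
    pixel_count: int
    weighted_area: float
    euler_number: int


@dataclass
class DetectionResult:
    mask: BinaryMask
    spots: list[Spot]
    branch_masks: tuple[BinaryMask, BinaryMask]  # (spatial, wavelet)


def _check_min_shape(arr: np.ndarray, min_side: int, what: str) -> None:
    if arr.ndim != 2 or min(arr.shape) < min_side:
        raise DimensionError(
            f"{what} requires a 2-D image with sides >= {min_side}, "
            f"got shape {arr.shape}")


def laplacian_sharpen(roi, eight_neighbor: bool = False) -> np.ndarray:
    """Sharpened image ``f1 = roi - laplacian(roi)`` (symmetric borders)."""
    arr = as_pixels(roi).astype(float)
    _check_min_shape(arr, 3, "laplacian_sharpen")
    kernel = _LAPLACIAN_8 if eight_neighbor else _LAPLACIAN_4
    return arr - ndimage.convolve(arr, kernel, mode="reflect")


def smooth3x3(roi) -> np.ndarray:
    """3x3 box-mean smoothing ``f2`` (symmetric borders)."""
    arr = as_pixels(roi).astype(float)
    _check_min_shape(arr, 3, "smooth3x3")
    return ndimage.uniform_filter(arr, size=3, mode="reflect")


def difference_image(f1, f2) -> np.ndarray:
    """Signed difference ``f3 = f1 - f2``."""
    a, b = as_pixels(f1).astype(float), as_pixels(f2).astype(float)
    if a.shape != b.shape:
        raise DimensionError(f"shape mismatch {a.shape} vs {b.shape}")
    return a - b


def _kirsch_masks() -> list[np.ndarray]:
    """The eight compass masks: +5 weights rotate around the ring."""
    ring = [(0, 0), (0, 1), (0, 2), (1, 2), (2, 2), (2, 1), (2, 0), (1, 0)]
    masks = []
    for rot in range(8):
        m = np.zeros((3, 3))
        for i, (r, c) in enumerate(ring):
            m[r, c] = 5.0 if (i - rot) % 8 < 3 else -3.0
        masks.append(m)
    return masks


_KIRSCH = _kirsch_masks()


def kirsch_edges(image) -> np.ndarray:
    """Maximum response over the eight rotated Kirsch 3x3 masks."""
    arr = as_pixels(image).astype(float)
    _check_min_shape(arr, 3, "kirsch_edges")
    responses = [ndimage.correlate(arr, m, mode="reflect") for m in _KIRSCH]
    return np.max(responses, axis=0)


def binarize(image, method: str = "otsu", percentile: float = 97.0) -> BinaryMask:
    """Threshold an image; foreground = pixels >= threshold.

    ``otsu`` maximizes between-class variance over a 256-bin histogram;
    ``percentile`` thresholds at the given percentile of the pixel values.
    """
    arr = as_pixels(image).astype(float)
    if method == "otsu":
        if arr.max() == arr.min():
            raise DegenerateInputError("Otsu threshold undefined on constant image")
        thresh = threshold_otsu(arr, nbins=256)
    elif method == "percentile":
        thresh = np.percentile(arr, percentile)
    else:
        raise ValueError(f"unknown binarization method {method!r}")
    return BinaryMask((arr >= thresh).astype(np.uint8))


def wavelet_bandpass(roi, wavelet: str = "db4", levels: int = 4,
                     zero_levels: tuple[int, ...] = (1, 4),
                     zero_approx: bool = True) -> np.ndarray:
    """Band-pass reconstruction via a zeroed multi-level DWT.

    Detail layers listed in ``zero_levels`` (1 = finest) are removed; if the
    coarsest layer is listed and ``zero_approx`` is set, the approximation is
    removed too, discarding the low-frequency background.
    """
    arr = as_pixels(roi).astype(float)
    if min(arr.shape) < 2 ** levels:
        raise DimensionError(
            f"image shape {arr.shape} cannot support a {levels}-level DWT")
    coeffs = pywt.wavedec2(arr, wavelet, level=levels, mode="symmetric")
    # coeffs = [cA_L, details_L, ..., details_1]
    for lev in zero_levels:
        if not 1 <= lev <= levels:
            raise ValueError(f"zero level {lev} outside 1..{levels}")
        idx = levels - lev + 1
        coeffs[idx] = tuple(np.zeros_like(b) for b in coeffs[idx])
    if zero_approx and levels in zero_levels:
        coeffs[0] = np.zeros_like(coeffs[0])
    rec = pywt.waverec2(coeffs, wavelet, mode="symmetric")
    return rec[: arr.shape[0], : arr.shape[1]]


def weighted_area(mask) -> float:
    """Area with boundary compensation: interior pixels (all 4-neighbors
    foreground) weigh 1.0, boundary foreground pixels weigh 0.5."""
    arr = np.asarray(as_pixels(mask)).astype(bool)
    if not arr.any():
        raise EmptyRegionError("weighted area of an empty mask is undefined")
    interior = ndimage.binary_erosion(arr, structure=_FOUR, border_value=0)
    boundary = arr & ~interior
    return float(interior.sum() + 0.5 * boundary.sum())


def euler_number(mask) -> int:
    """Euler number E = C - H: 8-connected foreground components minus
    4-connected background holes."""
    arr = np.asarray(as_pixels(mask)).astype(bool)
    if not arr.any():
        return 0
    _, n_components = ndimage.label(arr, structure=_EIGHT)
    padded = np.pad(arr, 1, constant_values=False)
    _, n_background = ndimage.label(~padded, structure=_FOUR)
    n_holes = n_background - 1  # the border-connected background is not a hole
    return int(n_components - n_holes)


def _branch_mask(image: np.ndarray, method: str, percentile: float) -> BinaryMask:
    """Binarize one branch; a zero-range branch image means no evidence at
    all, which maps to an empty mask rather than an all-foreground one."""
    if image.max() == image.min():
        return BinaryMask(np.zeros(image.shape, dtype=np.uint8))
    return binarize(image, method=method, percentile=percentile)


def detect(roi, config: DetectionConfig | None = None) -> DetectionResult:
    """Run the fused two-branch detector on a (normalized) ROI."""
    config = config or DetectionConfig()
    arr = as_pixels(roi).astype(float)

    f1 = laplacian_sharpen(arr, eight_neighbor=config.eight_neighbor_laplacian)
    f2 = smooth3x3(arr)
    edges = kirsch_edges(difference_image(f1, f2))
    spatial = _branch_mask(edges, "percentile", config.edge_percentile)

    band = wavelet_bandpass(arr, wavelet=config.dwt_wavelet,
                            levels=config.dwt_levels,
                            zero_levels=config.zero_levels,
                            zero_approx=config.zero_approx)
    wavelet = _branch_mask(band, config.wavelet_method, config.wavelet_percentile)

    fused = BinaryMask(spatial.pixels & wavelet.pixels)
    labels, n = ndimage.label(fused.pixels, structure=_EIGHT)
    spots: list[Spot] = []
    for lab in range(1, n + 1):
        component = labels == lab
        count = int(component.sum())
        if count < config.min_spot_px:
            continue
        r, c = ndimage.center_of_mass(component)
        rows, cols = np.nonzero(component)
        box = component[rows.min():rows.max() + 1, cols.min():cols.max() + 1]
        spots.append(Spot(centroid=(float(r), float(c)),
                          pixel_count=count,
                          weighted_area=weighted_area(box),
                          euler_number=euler_number(box)))
    return DetectionResult(mask=fused, spots=spots,
                           branch_masks=(spatial, wavelet))
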