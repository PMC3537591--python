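"""The 14-element ROI descriptor.

Order: ``[m2, m4, T1..T9, W1, W2, W3]`` —

* ``m2``, ``m4``: second and fourth central moments of the 256-level gray
  histogram (visual roughness and histogram uniformity);
* ``T1..T9``: gray-level co-occurrence descriptors — angular second moment,
  inertia, inverse difference moment, entropy, correlation, sum average,
  difference average, sum entropy, difference entropy (natural logs);
* ``W1..W3``: dual-tree complex wavelet energy summaries over the 12
  oriented sub-bands of a 2-level decomposition — total magnitude energy,
  level-1/level-2 energy ratio, and orientation-energy entropy.

GLCMs use the standard Haralick configuration by default: 16 gray levels,
displacement 1, four angles accumulated symmetrically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.feature import graycomatrix

from .dtcwt_core import FilterBank, dtcwt2d_forward
from .errors import DegenerateInputError, DimensionError
from .image_io import as_pixels

__all__ = [
    "FEATURE_NAMES",
    "HistogramStats",
    "GLCM",
    "FeatureVector",
    "quantize_levels",
    "histogram_stats",
    "histogram_moment",
    "compute_glcm",
    "glcm_descriptors",
    "wavelet_features",
    "extract_features",
]

FEATURE_NAMES: tuple[str, ...] = (
    "m2", "m4",
    "T1", "T2", "T3", "T4", "T5", "T6", "T7", "T8", "T9",
    "W1", "W2", "W3",
)

_ANGLES = {0: 0.0, 45: np.pi / 4, 90: np.pi / 2, 135: 3 * np.pi / 4}


@dataclass
class HistogramStats:
    """Normalized gray histogram with its mean, over K levels."""

    K: int
    h: np.ndarray      # normalized frequencies, sums to 1
    mu: float
    N: int


@dataclass
class GLCM:
    """Symmetric, angle-accumulated co-occurrence probability matrix."""

    C: np.ndarray
    levels: int
    distance: int
    angles: tuple[int, ...]
    symmetric: bool = True


@dataclass
class FeatureVector:
    """Ordered 14-element descriptor of one ROI."""

    values: np.ndarray
    names: tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.names),):
            raise DimensionError(
                f"feature vector must have length {len(self.names)}, "
                f"got {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise DegenerateInputError("feature vector contains non-finite values")


def quantize_levels(roi, levels: int) -> np.ndarray:
    """Uniformly quantize a [0, 255] image to integer levels 0..levels-1."""
    arr = as_pixels(roi).astype(float)
    return np.clip(np.floor(arr * levels / 256.0), 0, levels - 1).astype(np.intp)


def histogram_stats(roi, levels: int = 256) -> HistogramStats:
    """Gray histogram over ``levels`` uniform bins with its mean."""
    q = quantize_levels(roi, levels)
    if q.size == 0:
        raise DegenerateInputError("empty ROI has no histogram")
    counts = np.bincount(q.ravel(), minlength=levels).astype(float)
    n = q.size
    h = counts / n
    mu = float((np.arange(levels) * h).sum())
    return HistogramStats(K=levels, h=h, mu=mu, N=n)


def histogram_moment(roi, n: int, levels: int = 256) -> float:
    """n-th central moment of the gray-level histogram.

    With raw counts ``h(k)`` this is the standard central moment
    ``m_n = (1/N) * sum_k (k - mu)^n h(k)`` (variance for n=2, the
    kurtosis-type fourth moment for n=4).
    """
    if n not in (2, 3, 4):
        raise ValueError(f"moment order must be 2, 3 or 4, got {n}")
    stats = histogram_stats(roi, levels)
    k = np.arange(stats.K)
    return float(((k - stats.mu) ** n * stats.h).sum())


def _quantize_range(arr: np.ndarray, levels: int) -> np.ndarray:
    """Quantize to ``levels`` uniform bins spanning the image's own range.

    For gray-normalized input (min 0, max 255) this coincides with uniform
    quantization of [0, 255]; a constant image maps to a single level.
    """
    lo, hi = float(arr.min()), float(arr.max())
    if hi == lo:
        return np.zeros(arr.shape, dtype=np.intp)
    q = np.floor((arr - lo) * (levels / (hi - lo)))
    return np.clip(q, 0, levels - 1).astype(np.intp)


def compute_glcm(roi, levels: int = 16, distance: int = 1,
                 angles: tuple[int, ...] = (0, 45, 90, 135)) -> GLCM:
    """Co-occurrence probabilities at displacement ``distance``, symmetrized
    and accumulated over ``angles`` (degrees), normalized to sum 1."""
    if not 2 <= levels <= 256:
        raise ValueError(f"unsupported GLCM level count {levels}")
    arr = as_pixels(roi).astype(float)
    if min(arr.shape) <= distance:
        raise DimensionError(
            f"ROI shape {arr.shape} smaller than GLCM displacement {distance}")
    q = _quantize_range(arr, levels).astype(np.uint8)
    rads = [_ANGLES[a] for a in angles]
    counts = graycomatrix(q, distances=[distance], angles=rads,
                          levels=levels, symmetric=True, normed=False)
    acc = counts[:, :, 0, :].sum(axis=-1).astype(float)
    total = acc.sum()
    if total == 0:
        raise DimensionError("no co-occurring pixel pairs at this displacement")
    return GLCM(C=acc / total, levels=levels, distance=distance,
                angles=tuple(angles), symmetric=True)


def _sum_diff_distributions(C: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    k = C.shape[0]
    i, j = np.indices((k, k))
    c_sum = np.bincount((i + j).ravel(), weights=C.ravel(), minlength=2 * k - 1)
    c_diff = np.bincount(np.abs(i - j).ravel(), weights=C.ravel(), minlength=k)
    return c_sum, c_diff


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def glcm_descriptors(glcm: GLCM | np.ndarray) -> np.ndarray:
    """The nine co-occurrence descriptors T1..T9 (natural logarithms).

    T5 (correlation) falls back to 0 with a warning when a marginal is
    degenerate (sigma_x * sigma_y = 0, e.g. a constant image).
    """
    C = glcm.C if isinstance(glcm, GLCM) else np.asarray(glcm, dtype=float)
    k = C.shape[0]
    i, j = np.indices((k, k))
    lvl = np.arange(k, dtype=float)
    px, py = C.sum(axis=1), C.sum(axis=0)
    mu_x, mu_y = float(lvl @ px), float(lvl @ py)
    sig_x = float(np.sqrt(((lvl - mu_x) ** 2) @ px))
    sig_y = float(np.sqrt(((lvl - mu_y) ** 2) @ py))
    c_sum, c_diff = _sum_diff_distributions(C)

    t1 = float((C ** 2).sum())
    t2 = float(((i - j) ** 2 * C).sum())
    t3 = float((C / (1.0 + (i - j) ** 2)).sum())
    t4 = _entropy(C.ravel())
    if sig_x > 0 and sig_y > 0:
        t5 = float(((i * j * C).sum() - mu_x * mu_y) / (sig_x * sig_y))
    else:
        warnings.warn("degenerate GLCM marginals; correlation T5 set to 0",
                      stacklevel=2)
        t5 = 0.0
    ks = np.arange(2 * k - 1, dtype=float)
    kd = np.arange(k, dtype=float)
    t6 = float(ks @ c_sum)
    t7 = float(kd @ c_diff)
    t8 = _entropy(c_sum)
    t9 = _entropy(c_diff)
    return np.array([t1, t2, t3, t4, t5, t6, t7, t8, t9])


def wavelet_features(roi, levels: int = 2,
                     bank: FilterBank | None = None) -> np.ndarray:
    """Three energy summaries of the 12 oriented complex sub-bands.

    ``W1`` total mean magnitude energy; ``W2`` level-1 over level-2 energy
    ratio (0 when level 2 is empty); ``W3`` entropy of the normalized
    per-sub-band energy distribution (0 for an all-zero pyramid, maximal
    ln 12 when all sub-bands carry equal energy).
    """
    arr = as_pixels(roi)
    if min(arr.shape) < 32:
        raise DimensionError(
            f"wavelet features need an ROI of at least 32x32, got {arr.shape}")
    pyramid = dtcwt2d_forward(arr, levels=levels, bank=bank)
    energies = np.array([np.mean(np.abs(band) ** 2)
                         for level in pyramid.levels
                         for band in level.values()])
    total = float(energies.sum())
    if total == 0.0:
        return np.array([0.0, 0.0, 0.0])
    per_level = [sum(np.mean(np.abs(b) ** 2) for b in level.values())
                 for level in pyramid.levels]
    w2 = per_level[0] / per_level[1] if per_level[1] > 0 else 0.0
    return np.array([total, float(w2), _entropy(energies / total)])


def extract_features(roi, glcm_levels: int = 16, glcm_distance: int = 1,
                     dtcwt_levels: int = 2,
                     bank: FilterBank | None = None) -> FeatureVector:
    """Full ordered 14-descriptor vector for a gray-normalized ROI."""
    m2 = histogram_moment(roi, 2)
    m4 = histogram_moment(roi, 4)
    t = glcm_descriptors(compute_glcm(roi, levels=glcm_levels,
                                      distance=glcm_distance))
    w = wavelet_features(roi, levels=dtcwt_levels, bank=bank)
    return FeatureVector(values=np.concatenate([[m2, m4], t, w]))
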