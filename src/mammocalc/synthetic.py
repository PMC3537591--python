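"""Ground-truthed synthetic mammography-like ROIs.

Real microcalcification patches are small bright deposits with soft
profiles on textured parenchyma.  The generator emulates that structure as
a sum of a broad smooth random field (parenchymal density), mid-frequency
smoothed noise (fine tissue texture) and white noise, plus additive
Gaussian-profile spots.  Two lesion styles encode the morphology
distinction radiologists report (size, shape, distribution):

* benign: round single-lobe spots scattered across the ROI with a minimum
  pairwise distance;
* malignant: irregular multi-lobe spots clustered inside a small disk.

Every ROI is generated from its own seeded generator, so regeneration from
``(seed, parameters)`` is bit-identical.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import DimensionError, PlacementError
from .image_io import GrayImage, read_image, write_image

__all__ = [
    "Truth",
    "SyntheticROI",
    "BackgroundParams",
    "generate_background",
    "plant_spots",
    "generate_dataset",
    "write_dataset",
    "load_dataset",
]

_BORDER_MARGIN = 8          # px: truth centres stay this far from borders
_BENIGN_MIN_DIST = 12.0     # px: minimum pairwise distance, scattered style
_MALIGNANT_CLUSTER_R = 20.0  # px: cluster disk radius, clustered style
_MAX_ATTEMPTS = 1000


@dataclass
class Truth:
    """One planted spot: centre (row, col), nominal radius and contrast."""

    row: float
    col: float
    radius_px: float
    contrast: float


@dataclass
class SyntheticROI:
    image: GrayImage
    truths: list[Truth]
    label: str                  # normal | benign | malignant
    seed: int
    ref_id: str = ""


@dataclass
class BackgroundParams:
    """Background composition: mean level plus three texture scales.

    Amplitudes are peak-scale gray levels: each smoothed noise field is
    standardized and scaled to ``amplitude / 4`` per standard deviation, so
    its typical peak-to-peak range is about the stated amplitude.
    """

    mean_level: float = 120.0
    low_amplitude: float = 80.0     # broad parenchyma-like structure
    mid_amplitude: float = 15.0     # fine tissue texture
    noise_sigma: float = 4.0        # white noise
    low_smoothing: float = 16.0     # Gaussian kernel sigmas, px
    mid_smoothing: float = 2.0


def _scaled_field(rng: np.random.Generator, size: int, smoothing: float,
                  amplitude: float) -> np.ndarray:
    """Smoothed noise rescaled to a deterministic peak-to-peak range of
    ``amplitude``, centred on zero.

    Deterministic range scaling (rather than scaling the field's standard
    deviation) keeps the realized dynamic range — and therefore the gray
    normalization stretch — stable across ROIs of the same class.
    """
    f = gaussian_filter(rng.normal(size=(size, size)), sigma=smoothing,
                        mode="reflect")
    return (f - f.min()) * (amplitude / (f.max() - f.min())) - amplitude / 2.0


def generate_background(size: int = 128, seed: int = 0,
                        params: BackgroundParams | None = None) -> GrayImage:
    """Seeded textured background, clipped to the 8-bit range."""
    if size < 32:
        raise DimensionError(f"background size must be >= 32, got {size}")
    params = params or BackgroundParams()
    rng = np.random.default_rng(seed)
    img = np.full((size, size), params.mean_level, dtype=float)
    for amplitude, smoothing in ((params.low_amplitude, params.low_smoothing),
                                 (params.mid_amplitude, params.mid_smoothing)):
        if amplitude > 0:
            img += _scaled_field(rng, size, smoothing, amplitude)
        else:
            rng.normal(size=(size, size))  # keep the draw sequence stable
    if params.noise_sigma > 0:
        img += rng.normal(0.0, params.noise_sigma, size=(size, size))
    return GrayImage(np.clip(img, 0.0, 255.0))


def _gaussian_spot(shape: tuple[int, int], row: float, col: float,
                   sigma: float, amplitude: float) -> np.ndarray:
    rr, cc = np.ogrid[0:shape[0], 0:shape[1]]
    return amplitude * np.exp(-((rr - row) ** 2 + (cc - col) ** 2)
                              / (2.0 * sigma ** 2))


def _sharp_lobe(shape: tuple[int, int], row: float, col: float,
                sigma: float, amplitude: float) -> np.ndarray:
    """Sharply marginated quasi-disk profile (cubed Gaussian argument),
    emulating the crisp edges of fine pleomorphic deposits."""
    rr, cc = np.ogrid[0:shape[0], 0:shape[1]]
    u = ((rr - row) ** 2 + (cc - col) ** 2) / (2.0 * sigma ** 2)
    return amplitude * np.exp(-u ** 3)


def _scattered_centers(rng: np.random.Generator, n: int, size: int
                       ) -> list[tuple[float, float]]:
    centers: list[tuple[float, float]] = []
    for _ in range(_MAX_ATTEMPTS):
        if len(centers) == n:
            break
        cand = tuple(rng.uniform(_BORDER_MARGIN, size - 1 - _BORDER_MARGIN,
                                 size=2))
        if all(np.hypot(cand[0] - r, cand[1] - c) >= _BENIGN_MIN_DIST
               for r, c in centers):
            centers.append(cand)
    if len(centers) < n:
        raise PlacementError(
            f"could not place {n} scattered spots in {_MAX_ATTEMPTS} attempts")
    return centers


def _clustered_centers(rng: np.random.Generator, n: int, size: int
                       ) -> list[tuple[float, float]]:
    lo = _BORDER_MARGIN + _MALIGNANT_CLUSTER_R
    hi = size - 1 - _BORDER_MARGIN - _MALIGNANT_CLUSTER_R
    if hi <= lo:
        raise PlacementError(f"ROI of size {size} too small for a cluster")
    center = rng.uniform(lo, hi, size=2)
    points: list[tuple[float, float]] = []
    for _ in range(_MAX_ATTEMPTS):
        if len(points) == n:
            break
        angle = rng.uniform(0, 2 * np.pi)
        radius = _MALIGNANT_CLUSTER_R * np.sqrt(rng.uniform())
        cand = (center[0] + radius * np.sin(angle),
                center[1] + radius * np.cos(angle))
        if (_BORDER_MARGIN <= cand[0] <= size - 1 - _BORDER_MARGIN
                and _BORDER_MARGIN <= cand[1] <= size - 1 - _BORDER_MARGIN):
            points.append(cand)
    if len(points) < n:
        raise PlacementError(
            f"could not place {n} clustered spots in {_MAX_ATTEMPTS} attempts")
    return points


def plant_spots(background: GrayImage, label: str, n_spots: int,
                seed: int = 0) -> SyntheticROI:
    """Add ``n_spots`` bright spots in the requested lesion style.

    Benign: coarse, smooth, round spots (soft Gaussian profile), radius
    U(2,4) px, contrast U(40,70), scattered with a minimum pairwise
    distance.  Malignant: fine-pleomorphic spots — each the union
    (pointwise max) of 2-4 jittered, sharply marginated lobes at full
    contrast — radius U(1,5), contrast U(30,80), clustered inside a small
    disk.  Intensities are additive and clipped to the 8-bit range.
    """
    if n_spots < 1:
        raise ValueError(f"n_spots must be >= 1, got {n_spots}")
    if label not in ("benign", "malignant"):
        raise ValueError(f"lesion label must be benign or malignant, got {label}")
    img = background.pixels.astype(float).copy()
    size = img.shape[0]
    rng = np.random.default_rng(seed)
    truths: list[Truth] = []
    if label == "benign":
        centers = _scattered_centers(rng, n_spots, size)
        for row, col in centers:
            radius = rng.uniform(2.0, 4.0)
            contrast = rng.uniform(40.0, 70.0)
            img += _gaussian_spot(img.shape, row, col, 0.6 * radius, contrast)
            truths.append(Truth(row, col, radius, contrast))
    else:
        centers = _clustered_centers(rng, n_spots, size)
        for row, col in centers:
            radius = rng.uniform(1.0, 5.0)
            contrast = rng.uniform(30.0, 80.0)
            n_lobes = int(rng.integers(2, 5))
            lobes = []
            lobe_centers = []
            for _ in range(n_lobes):
                lobe_row = row + rng.normal(0.0, radius)
                lobe_col = col + rng.normal(0.0, radius)
                lobe_sigma = rng.uniform(1.0, 1.5) * radius / 2.0
                lobes.append(_sharp_lobe(img.shape, lobe_row, lobe_col,
                                         lobe_sigma, contrast))
                lobe_centers.append((lobe_row, lobe_col, lobe_sigma))
            img += np.max(lobes, axis=0)
            # ground truth records the realized brightness centroid and
            # spread of the lobes, not the nominal draw centre
            crow = float(np.mean([c[0] for c in lobe_centers]))
            ccol = float(np.mean([c[1] for c in lobe_centers]))
            spread = max(np.hypot(c[0] - crow, c[1] - ccol) + 2.0 * c[2]
                         for c in lobe_centers)
            truths.append(Truth(crow, ccol, max(radius, spread), contrast))
    return SyntheticROI(image=GrayImage(np.clip(img, 0.0, 255.0)),
                        truths=truths, label=label, seed=seed)


def generate_dataset(n_normal: int = 25, n_abnormal: int = 25,
                     benign_fraction: float = 0.5, seed: int = 0,
                     size: int = 128,
                     params: BackgroundParams | None = None
                     ) -> list[SyntheticROI]:
    """Reproducible labeled dataset; abnormal ROIs carry 4-12 spots each.

    Per-ROI seeds are derived as ``seed + index`` so any single ROI can be
    regenerated independently.
    """
    if n_normal < 0 or n_abnormal < 0:
        raise ValueError("ROI counts must be non-negative")
    rois: list[SyntheticROI] = []
    n_benign = round(n_abnormal * benign_fraction)
    for idx in range(n_normal + n_abnormal):
        roi_seed = seed + idx
        background = generate_background(size=size, seed=roi_seed, params=params)
        if idx < n_normal:
            roi = SyntheticROI(image=background, truths=[], label="normal",
                               seed=roi_seed)
        else:
            label = "benign" if (idx - n_normal) < n_benign else "malignant"
            spot_rng = np.random.default_rng(roi_seed + 500_000)
            n_spots = int(spot_rng.integers(4, 13))
            roi = plant_spots(background, label, n_spots,
                              seed=roi_seed + 1_000_000)
        roi.ref_id = f"syn{idx:03d}"
        rois.append(roi)
    return rois


def write_dataset(rois: list[SyntheticROI], out_dir: str | Path,
                  manifest: dict | None = None) -> None:
    """Write PGM images plus ``truths.csv`` and ``manifest.json``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "truths.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["ref_id", "label", "row", "col", "radius", "contrast"])
        for roi in rois:
            write_image(roi.image, out / f"{roi.ref_id}.pgm")
            if not roi.truths:
                writer.writerow([roi.ref_id, roi.label, "", "", "", ""])
            for t in roi.truths:
                writer.writerow([roi.ref_id, roi.label,
                                 f"{t.row:.3f}", f"{t.col:.3f}",
                                 f"{t.radius_px:.3f}", f"{t.contrast:.3f}"])
    meta = {"n_rois": len(rois),
            "seeds": {roi.ref_id: roi.seed for roi in rois}}
    if manifest:
        meta.update(manifest)
    with open(out / "manifest.json", "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_dataset(in_dir: str | Path) -> list[SyntheticROI]:
    """Read back a dataset written by :func:`write_dataset`."""
    src = Path(in_dir)
    truths_file = src / "truths.csv"
    if not truths_file.exists():
        raise FileNotFoundError(f"no truths.csv in {src}")
    by_id: dict[str, dict] = {}
    with open(truths_file, newline="") as fh:
        for rec in csv.DictReader(fh):
            entry = by_id.setdefault(
                rec["ref_id"], {"label": rec["label"], "truths": []})
            if rec["row"]:
                entry["truths"].append(Truth(float(rec["row"]),
                                             float(rec["col"]),
                                             float(rec["radius"]),
                                             float(rec["contrast"])))
    rois = []
    manifest_path = src / "manifest.json"
    seeds = {}
    if manifest_path.exists():
        seeds = json.loads(manifest_path.read_text()).get("seeds", {})
    for ref_id in sorted(by_id):
        image = read_image(src / f"{ref_id}.pgm")
        entry = by_id[ref_id]
        rois.append(SyntheticROI(image=image, truths=entry["truths"],
                                 label=entry["label"],
                                 seed=int(seeds.get(ref_id, -1)),
                                 ref_id=ref_id))
    return rois
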