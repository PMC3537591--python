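"""ROC and FROC evaluation with detection/ground-truth matching.

The ROC curve scores ROI-level classification on the SVM's signed decision
value; its AUC (trapezoidal rule) equals the Mann-Whitney pair-counting
statistic.  The FROC curve scores spot-level detection: the detector's
operating parameter (by default the spatial-branch edge percentile) is
swept from strict to permissive and, at each setting, lesion sensitivity is
plotted against false positives per image, pooled over the dataset.

A detected spot counts as a true positive when its centroid lies within
``max(truth radius, tolerance)`` of an unclaimed ground-truth centre;
matching is greedy nearest-first and one-to-one.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from sklearn import metrics as _skmetrics

from .detection import DetectionConfig, Spot, detect
from .errors import LabelError
from .image_io import normalize_gray

__all__ = [
    "ROCCurve",
    "FROCCurve",
    "roc_curve",
    "match_detections",
    "froc_curve",
]


@dataclass
class ROCCurve:
    points: np.ndarray      # (n, 2) columns (FPF, TPF), includes (0,0),(1,1)
    thresholds: np.ndarray
    auc: float


@dataclass
class FROCCurve:
    points: np.ndarray      # (n, 2) columns (fp_per_image, sensitivity)
    settings: np.ndarray    # swept operating-parameter values


def roc_curve(scores, labels) -> ROCCurve:
    """Threshold-sweep ROC over unique score values; ties share a step."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    if np.unique(y).size < 2:
        raise LabelError("ROC needs both classes present")
    fpf, tpf, thresholds = _skmetrics.roc_curve(y, scores)
    return ROCCurve(points=np.column_stack([fpf, tpf]),
                    thresholds=thresholds,
                    auc=float(_skmetrics.auc(fpf, tpf)))


def match_detections(spots, truths, tolerance_px: float = 5.0
                     ) -> tuple[int, int, int]:
    """Greedy nearest-first one-to-one matching of spots to lesion truths.

    ``truths`` is a sequence of ``(row, col, radius)`` triples (any object
    with ``row``/``col``/``radius_px`` attributes also works).  Returns
    (TP, FP, FN).
    """
    if tolerance_px <= 0:
        raise ValueError("matching tolerance must be positive")
    cents = [s.centroid if isinstance(s, Spot) else tuple(s) for s in spots]
    parsed = []
    for t in truths:
        if hasattr(t, "row"):
            parsed.append((float(t.row), float(t.col), float(t.radius_px)))
        else:
            row, col, radius = t[:3]
            parsed.append((float(row), float(col), float(radius)))
    pairs = []
    for i, (sr, sc) in enumerate(cents):
        for j, (tr, tc, rad) in enumerate(parsed):
            dist = float(np.hypot(sr - tr, sc - tc))
            if dist <= max(rad, tolerance_px):
                pairs.append((dist, i, j))
    pairs.sort()
    used_spots: set[int] = set()
    used_truths: set[int] = set()
    tp = 0
    for _, i, j in pairs:
        if i in used_spots or j in used_truths:
            continue
        used_spots.add(i)
        used_truths.add(j)
        tp += 1
    return tp, len(cents) - tp, len(parsed) - tp


def froc_curve(dataset, sweep, config: DetectionConfig | None = None,
               tolerance_px: float = 5.0, parameter: str = "edge_percentile",
               normalized: bool = False) -> FROCCurve:
    """Sweep a detector operating parameter and pool matches per setting.

    ``dataset`` is an iterable of ``(image, truths)`` pairs or objects with
    ``image``/``truths`` attributes (e.g. synthetic ROIs).  Sensitivity is
    pooled as sum(TP)/sum(truths) and false positives as sum(FP)/n_images.
    """
    sweep = np.asarray(list(sweep), dtype=float)
    if sweep.size == 0:
        raise ValueError("sweep must contain at least one setting")
    config = config or DetectionConfig()
    items = []
    for entry in dataset:
        if hasattr(entry, "image"):
            image, truths = entry.image, entry.truths
        else:
            image, truths = entry
        if not normalized:
            image = normalize_gray(image)
        items.append((image, truths))
    if not items:
        raise ValueError("dataset must contain at least one image")
    points = []
    for setting in sweep:
        cfg = replace(config, **{parameter: float(setting)})
        total_tp = total_fp = total_truths = 0
        for image, truths in items:
            result = detect(image, cfg)
            tp, fp, _ = match_detections(result.spots, truths, tolerance_px)
            total_tp += tp
            total_fp += fp
            total_truths += len(list(truths))
        sensitivity = total_tp / total_truths if total_truths else 0.0
        points.append((total_fp / len(items), sensitivity))
    order = np.argsort([p[0] for p in points], kind="stable")
    pts = np.asarray(points, dtype=float)[order]
    return FROCCurve(points=pts, settings=sweep[order])
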