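"""PCA reduction and two-stage polynomial-kernel SVM classification.

The 14 descriptors live on wildly different scales (histogram moments in
the thousands, co-occurrence probabilities below one), so features are
z-scored and the PCA diagonalizes the correlation matrix.  Four components
are retained; an explained-variance-weighted sum of the component scores
gives a single "comprehensive score" used for visualization and ROC
scoring, while the SVM consumes the four component scores.

Stage 1 separates normal from abnormal ROIs over the whole sample; stage 2
separates benign from malignant over the abnormal subset.  Both stages are
validated by leave-one-out cross-validation with standardization and PCA
refitted inside every fold (no leakage of the held-out sample).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA
from sklearn.svm import SVC

from .errors import DegenerateFeatureError, DimensionError, LabelError

__all__ = [
    "PCAModel",
    "ClassifierModel",
    "CVReport",
    "pca_fit",
    "pca_transform",
    "comprehensive_score",
    "svm_train",
    "svm_decision",
    "loocv",
    "two_stage_classify",
]


@dataclass
class PCAModel:
    """Standardization parameters plus orthonormal component loadings."""

    means: np.ndarray
    scales: np.ndarray
    components: np.ndarray              # (n_components, n_features)
    explained_variance_ratio: np.ndarray

    @property
    def n_components(self) -> int:
        return self.components.shape[0]


@dataclass
class ClassifierModel:
    """A trained polynomial-kernel SVM with its hyperparameters."""

    kernel_degree: int
    C: float
    classes: np.ndarray
    svc: SVC = field(repr=False, default=None)


@dataclass
class CVReport:
    """Leave-one-out result: exact accuracy and per-sample decisions."""

    accuracy: float
    per_sample: list[tuple[object, object, float]]  # (true, predicted, decision)
    n_runs: int


def pca_fit(features: np.ndarray, n_components: int = 4) -> PCAModel:
    """Fit correlation-matrix PCA (z-score then eigendecompose).

    Deterministic sign convention: each component's largest-magnitude
    loading is positive.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2:
        raise DimensionError(f"feature matrix must be 2-D, got {X.shape}")
    n, p = X.shape
    if n < n_components + 1:
        raise DimensionError(
            f"need at least {n_components + 1} samples to retain "
            f"{n_components} components, got {n}")
    means = X.mean(axis=0)
    scales = X.std(axis=0, ddof=1)
    dead = np.nonzero(scales == 0)[0]
    if dead.size:
        raise DegenerateFeatureError(
            f"constant feature column(s) {dead.tolist()} cannot be standardized")
    Z = (X - means) / scales
    pca = PCA(n_components=n_components, svd_solver="full")
    pca.fit(Z)
    components = pca.components_.copy()
    for comp in components:
        if comp[np.argmax(np.abs(comp))] < 0:
            comp *= -1.0
    return PCAModel(means=means, scales=scales, components=components,
                    explained_variance_ratio=pca.explained_variance_ratio_.copy())


def pca_transform(model: PCAModel, x: np.ndarray) -> np.ndarray:
    """Project feature vector(s) onto the retained components."""
    x = np.asarray(x, dtype=float)
    squeeze = x.ndim == 1
    X = np.atleast_2d(x)
    if X.shape[1] != model.means.shape[0]:
        raise DimensionError(
            f"expected {model.means.shape[0]} features, got {X.shape[1]}")
    scores = (X - model.means) / model.scales @ model.components.T
    return scores[0] if squeeze else scores


def comprehensive_score(model: PCAModel, scores: np.ndarray) -> np.ndarray | float:
    """Explained-variance-weighted sum of the component scores."""
    scores = np.asarray(scores, dtype=float)
    ratio = model.explained_variance_ratio
    weights = ratio / ratio.sum()
    return scores @ weights


def svm_train(X: np.ndarray, y: np.ndarray, degree: int = 2,
              C: float = 1.0) -> ClassifierModel:
    """Train a soft-margin SVM with kernel ``(gamma x.x' + 1)^degree``,
    gamma = 1/n_features."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size < 2:
        raise LabelError(f"need two classes to train, got {classes.tolist()}")
    if degree not in (2, 3):
        raise ValueError(f"kernel degree must be 2 or 3, got {degree}")
    svc = SVC(kernel="poly", degree=degree, C=C, gamma=1.0 / X.shape[1],
              coef0=1.0)
    svc.fit(X, y)
    return ClassifierModel(kernel_degree=degree, C=C, classes=classes, svc=svc)


def svm_decision(model: ClassifierModel, X: np.ndarray) -> np.ndarray:
    """Signed decision values (positive favours ``model.classes[1]``)."""
    return model.svc.decision_function(np.atleast_2d(np.asarray(X, dtype=float)))


def svm_predict(model: ClassifierModel, X: np.ndarray) -> np.ndarray:
    return model.svc.predict(np.atleast_2d(np.asarray(X, dtype=float)))


def loocv(X: np.ndarray, y: np.ndarray, degree: int = 2, C: float = 1.0,
          n_components: int = 4, use_comprehensive: bool = False) -> CVReport:
    """Leave-one-out cross-validation of the PCA + SVM pipeline.

    Standardization and PCA are refitted on the 'n-1' training rows of every
    fold; the held-out sample never influences the fold's model.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = X.shape[0]
    if n < 3:
        raise DimensionError(f"leave-one-out needs at least 3 samples, got {n}")
    per_sample: list[tuple[object, object, float]] = []
    correct = 0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        if np.unique(y[mask]).size < 2:
            raise LabelError(f"fold {i} has a single training class")
        pca = pca_fit(X[mask], n_components=n_components)
        train_scores = pca_transform(pca, X[mask])
        test_scores = pca_transform(pca, X[i])
        if use_comprehensive:
            train_scores = comprehensive_score(pca, train_scores)[:, None]
            test_scores = np.atleast_1d(comprehensive_score(pca, test_scores))
        # standardize the SVM inputs: component scores have variances
        # proportional to their eigenvalues, and an unscaled polynomial
        # kernel would let the first component swamp the rest
        mu = train_scores.mean(axis=0)
        sd = train_scores.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        train_scores = (train_scores - mu) / sd
        test_scores = (np.atleast_2d(test_scores) - mu) / sd
        model = svm_train(train_scores, y[mask], degree=degree, C=C)
        pred = svm_predict(model, test_scores)[0]
        dec = float(svm_decision(model, test_scores)[0])
        per_sample.append((y[i], pred, dec))
        correct += int(pred == y[i])
    return CVReport(accuracy=correct / n, per_sample=per_sample, n_runs=n)


def two_stage_classify(features: np.ndarray, labels: np.ndarray,
                       stage1_degree: int = 2, stage2_degree: int = 3,
                       C: float = 1.0, n_components: int = 4,
                       use_comprehensive: bool = False) -> tuple[CVReport, CVReport]:
    """Two-stage LOOCV: normal vs abnormal over all samples, then benign vs
    malignant over the abnormal subset."""
    labels = np.asarray(labels, dtype=object)
    present = set(labels.tolist())
    missing = {"normal", "benign", "malignant"} - present
    if missing:
        raise LabelError(f"label value(s) missing from dataset: {sorted(missing)}")
    X = np.asarray(features, dtype=float)
    stage1_y = np.where(labels == "normal", "normal", "abnormal")
    report1 = loocv(X, stage1_y, degree=stage1_degree, C=C,
                    n_components=n_components, use_comprehensive=use_comprehensive)
    abnormal = labels != "normal"
    report2 = loocv(X[abnormal], labels[abnormal], degree=stage2_degree, C=C,
                    n_components=n_components, use_comprehensive=use_comprehensive)
    return report1, report2
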