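"""Gaussian-process classification of feature vectors.

A binary GP classifier with a constant x RBF kernel maps the (f1, f2, f3)
features to a posterior probability that the query is a spurious gene call.
Inference uses the Laplace approximation with a logistic link (scikit-learn's
``GaussianProcessClassifier``); kernel hyperparameters are optimised by
marginal likelihood with a fixed restart schedule under a caller-supplied
seed.  Features are z-scored with training-set statistics before entering the
kernel; those statistics are part of the persisted model, so a stored model
predicts deterministically.

Spurious is the positive class throughout.  A probability at or above the
call threshold (default 0.8) is reported as spurious.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import joblib
import numpy as np
from sklearn.gaussian_process import GaussianProcessClassifier
from sklearn.gaussian_process.kernels import RBF, ConstantKernel
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import precision_recall_curve, roc_curve
from sklearn.model_selection import StratifiedKFold

from .features import DEFAULT_EDGE_WIDTH, FeatureVector

LABEL_REAL = "real"
LABEL_SPURIOUS = "spurious"
DEFAULT_THRESHOLD = 0.8
DEFAULT_N_RESTARTS = 3
MODEL_FORMAT_VERSION = 1


class ModelFormatError(ValueError):
    """A model file is missing required blocks or has the wrong version."""


@dataclass(frozen=True)
class LabeledSample:
    features: FeatureVector
    label: str  # "spurious" | "real"
    source_id: str = ""

    def __post_init__(self) -> None:
        if self.label not in (LABEL_REAL, LABEL_SPURIOUS):
            raise ValueError(f"label must be {LABEL_REAL!r} or "
                             f"{LABEL_SPURIOUS!r}, got {self.label!r}")


@dataclass(frozen=True)
class Prediction:
    query_id: str
    p_spurious: float | None
    call: str  # "spurious" | "real" | "no_call"
    threshold: float = DEFAULT_THRESHOLD


def _design_matrix(samples: list[LabeledSample]) -> tuple[np.ndarray,
                                                          np.ndarray]:
    X = np.array([s.features.as_tuple() for s in samples], dtype=float)
    y = np.array([1 if s.label == LABEL_SPURIOUS else 0 for s in samples])
    bad = ~np.isfinite(X).all(axis=1)
    if bad.any():
        ids = [samples[i].source_id or f"#{i}" for i in np.where(bad)[0]]
        raise ValueError(f"non-finite features in samples: {ids}")
    return X, y


class SpuriousProteinClassifier:
    """Trained GP state: kernel, normalisation statistics, metadata."""

    def __init__(self, gpc: GaussianProcessClassifier, mean: np.ndarray,
                 scale: np.ndarray, metadata: dict):
        self._gpc = gpc
        self.mean = np.asarray(mean, dtype=float)
        self.scale = np.asarray(scale, dtype=float)
        self.metadata = metadata

    @property
    def kernel_(self):
        return self._gpc.kernel_

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """P(spurious) for rows of raw (f1, f2, f3) features."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Z = (X - self.mean) / self.scale
        return self._gpc.predict_proba(Z)[:, 1]

    def predict(self, features: FeatureVector | None, query_id: str = "",
                threshold: float = DEFAULT_THRESHOLD) -> Prediction:
        """Score one query; ``features=None`` means no homologs -> no_call."""
        if features is None:
            return Prediction(query_id, None, "no_call", threshold)
        p = float(self.predict_proba([features.as_tuple()])[0])
        call = LABEL_SPURIOUS if p >= threshold else LABEL_REAL
        return Prediction(query_id, p, call, threshold)


def fit(samples: list[LabeledSample], seed: int = 0,
        n_restarts: int = DEFAULT_N_RESTARTS) -> SpuriousProteinClassifier:
    """Train the GP classifier on labeled feature vectors."""
    if len(samples) < 4:
        raise ValueError("need at least 2 samples per class")
    X, y = _design_matrix(samples)
    return _fit_xy(X, y, seed=seed, n_restarts=n_restarts)


def _fit_xy(X: np.ndarray, y: np.ndarray, seed: int = 0,
            n_restarts: int = DEFAULT_N_RESTARTS
            ) -> SpuriousProteinClassifier:
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training data contains a single class")
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    Z = (X - mean) / scale
    kernel = ConstantKernel(1.0) * RBF(length_scale=1.0)
    gpc = GaussianProcessClassifier(
        kernel=kernel, n_restarts_optimizer=n_restarts, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # optimiser bound warnings
        gpc.fit(Z, y)
    metadata = dict(
        n_real=int((y == 0).sum()), n_spurious=int((y == 1).sum()),
        seed=seed, n_restarts=n_restarts, log_base="e",
        trim_edge_width=DEFAULT_EDGE_WIDTH,
        feature_names=("f1", "f2", "f3"),
    )
    return SpuriousProteinClassifier(gpc, mean, scale, metadata)


# ---------------------------------------------------------------------------
# metrics


def roc_auc(scores, labels) -> float:
    """Area under the empirical ROC curve (trapezoidal integration)."""
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("ROC AUC requires both classes present")
    fpr, tpr, _ = roc_curve(labels, np.asarray(scores, dtype=float))
    return float(_trapezoid_auc(fpr, tpr))


def roc_points(scores, labels) -> np.ndarray:
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, _ = roc_curve(labels, np.asarray(scores, dtype=float))
    return np.column_stack([fpr, tpr])


def pr_curve(scores, labels) -> np.ndarray:
    """(recall, precision) points of the precision-recall curve."""
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("PR curve requires both classes present")
    precision, recall, _ = precision_recall_curve(
        labels, np.asarray(scores, dtype=float))
    return np.column_stack([recall, precision])


def calibration_curve(scores, labels, bins: int = 10) -> np.ndarray:
    """Reliability diagram on equal-width bins of [0, 1].

    Returns rows (bin_mean_predicted, observed_spurious_frequency, count)
    for every non-empty bin.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("calibration requires both classes present")
    edges = np.linspace(0.0, 1.0, bins + 1)
    idx = np.clip(np.digitize(scores, edges[1:-1]), 0, bins - 1)
    rows = []
    for b in range(bins):
        mask = idx == b
        if mask.any():
            rows.append((scores[mask].mean(), labels[mask].mean(),
                         int(mask.sum())))
    return np.array(rows)


# ---------------------------------------------------------------------------
# cross-validation


@dataclass
class FoldResult:
    train_n: int
    test_n: int
    accuracy: float
    train_accuracy: float
    auc: float
    roc: np.ndarray
    pr: np.ndarray


@dataclass
class CVReport:
    k: int
    folds: list[FoldResult]
    oof_scores: np.ndarray  # out-of-fold P(spurious), one per sample
    oof_labels: np.ndarray
    calibration: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def mean_test_accuracy(self) -> float:
        return float(np.mean([f.accuracy for f in self.folds]))

    @property
    def mean_train_accuracy(self) -> float:
        return float(np.mean([f.train_accuracy for f in self.folds]))

    @property
    def mean_auc(self) -> float:
        return float(np.mean([f.auc for f in self.folds]))


def fold_sizes(n: int, k: int = 8) -> list[tuple[int, int]]:
    """(train_n, test_n) per fold when n samples are split into k folds."""
    if k > n:
        raise ValueError(f"cannot split {n} samples into {k} folds")
    base, extra = divmod(n, k)
    sizes = [base + 1] * extra + [base] * (k - extra)
    return [(n - t, t) for t in sizes]


def cross_validate(samples: list[LabeledSample], k: int = 8,
                   seed: int = 0,
                   n_restarts: int = DEFAULT_N_RESTARTS) -> CVReport:
    """Stratified k-fold cross-validation of the GP classifier.

    Every sample is tested exactly once; per-fold ROC/PR curves are kept so
    benchmark plots can show individual folds alongside the mean.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    X, y = _design_matrix(samples)
    if k > len(samples):
        raise ValueError(f"cannot split {len(samples)} samples into "
                         f"{k} folds")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    oof = np.full(len(samples), np.nan)
    folds = []
    for train_idx, test_idx in skf.split(X, y):
        m = _fit_xy(X[train_idx], y[train_idx], seed=seed,
                    n_restarts=n_restarts)
        p_test = m.predict_proba(X[test_idx])
        p_train = m.predict_proba(X[train_idx])
        oof[test_idx] = p_test
        folds.append(FoldResult(
            train_n=len(train_idx), test_n=len(test_idx),
            accuracy=float(((p_test >= 0.5).astype(int)
                            == y[test_idx]).mean()),
            train_accuracy=float(((p_train >= 0.5).astype(int)
                                  == y[train_idx]).mean()),
            auc=roc_auc(p_test, y[test_idx]),
            roc=roc_points(p_test, y[test_idx]),
            pr=pr_curve(p_test, y[test_idx]),
        ))
    report = CVReport(k=k, folds=folds, oof_scores=oof, oof_labels=y)
    report.calibration = calibration_curve(oof, y)
    return report


# ---------------------------------------------------------------------------
# persistence


def save_model(model: SpuriousProteinClassifier,
               path) -> None:
    """Persist a trained model as a versioned single-file archive."""
    joblib.dump(dict(
        format_version=MODEL_FORMAT_VERSION,
        normalization=dict(mean=model.mean.tolist(),
                           scale=model.scale.tolist()),
        metadata=model.metadata,
        gpc=model._gpc,
    ), path)


def load_model(path) -> SpuriousProteinClassifier:
    blob = joblib.load(path)
    if not isinstance(blob, dict) or "format_version" not in blob:
        raise ModelFormatError(f"{path}: not an orfscreen model file")
    if blob["format_version"] != MODEL_FORMAT_VERSION:
        raise ModelFormatError(
            f"{path}: model format version {blob['format_version']} is "
            f"incompatible with this build (expected "
            f"{MODEL_FORMAT_VERSION})")
    norm = blob.get("normalization")
    if not norm or "mean" not in norm or "scale" not in norm:
        raise ModelFormatError(f"{path}: missing normalization block")
    if "gpc" not in blob:
        raise ModelFormatError(f"{path}: missing classifier state")
    return SpuriousProteinClassifier(
        blob["gpc"], np.array(norm["mean"]), np.array(norm["scale"]),
        blob.get("metadata", {}))
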