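"""Parzen-window probabilistic neural network (PNN).

A PNN is a non-iterative kernel classifier: the pattern layer stores one
Gaussian kernel per training exemplar, the summation layer accumulates
the kernel responses per class,

    H_k(x) = sum_i exp(-||x - c_ki||^2 / (2 sigma^2)),

and the output layer forms Y_j = sum_k w_jk H_k(x).  With the default
weights w_jk = delta_jk / n_k the score Y_j is the average kernel response
of class j — a Parzen kernel-density estimate of the class-conditional
density up to a shared constant — so the argmax decision is the Bayes
rule under equal class priors.  Exact score ties are broken toward the
lowest class ordinal.

There is no error-driven weight training.  The only free parameter is the
smoothing width sigma, chosen here by an ascending grid search on the
leave-one-out misclassification rate, stopping at the first width that
meets the error goal (default 0.01, i.e. at most 1% LOO error).

An optional k-means reduction replaces each class's exemplars by a small
number of prototype centers, trading the full kernel density estimate for
a compact radial-basis-style pattern layer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.cluster.vq import kmeans2

from .features import FeatureVector, feature_matrix
from .tissue import CLASS_ORDER, TissueClass

__all__ = [
    "PNNModel",
    "pnn_train",
    "pattern_layer",
    "pnn_output",
    "pnn_predict",
    "select_sigma",
    "loo_error_rate",
    "model_to_json",
    "model_from_json",
]


@dataclass
class PNNModel:
    """Stored centers per class, smoothing width, and summation weights."""

    classes: list[TissueClass]
    centers: dict[TissueClass, np.ndarray]  # (n_k, feature_dim) each
    sigma: float
    weights: np.ndarray  # (M, M); weights[j, k] connects H_k to Y_j
    feature_dim: int

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        M = len(self.classes)
        if self.weights.shape != (M, M):
            raise ValueError(f"weights must be {M}x{M}")
        if np.any(self.weights < 0):
            raise ValueError("weights must be nonnegative")
        for tc in self.classes:
            c = self.centers[tc]
            if c.ndim != 2 or c.shape[1] != self.feature_dim:
                raise ValueError(f"centers for {tc.label} must be (n, {self.feature_dim})")
            if c.shape[0] < 1:
                raise ValueError(f"class {tc.label} has no centers")

    def n_centers(self) -> dict[TissueClass, int]:
        return {tc: self.centers[tc].shape[0] for tc in self.classes}


def _check_input(model: PNNModel, x: np.ndarray) -> np.ndarray:
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[1] != model.feature_dim:
        raise ValueError(f"input dimension {x.shape[1]} != model feature_dim {model.feature_dim}")
    return x


def pnn_train(
    features: list[FeatureVector],
    sigma: float,
    n_centers: int | None = None,
    seed: int = 0,
    classes: list[TissueClass] | None = None,
) -> PNNModel:
    """Build an exemplar PNN from labeled feature vectors.

    Every training vector becomes a center of its class; the default
    weights ``w_jk = delta_jk / n_k`` make each output the class-average
    kernel response.  With ``n_centers`` set, each class's exemplars are
    replaced by that many k-means prototypes (classes with fewer samples
    keep their exemplars).  ``classes`` fixes the expected class set (in
    ordinal order); by default the classes present in the data are used.
    """
    X, labels = feature_matrix(features)
    if any(lab is None for lab in labels):
        raise ValueError("all training samples must carry a tissue-class label")
    y = np.array([int(lab) for lab in labels])
    present = [tc for tc in CLASS_ORDER if int(tc) in set(y)]
    if classes is None:
        classes = present
    else:
        classes = sorted(classes, key=int)
        missing = [tc.label for tc in classes if tc not in present]
        if missing:
            raise ValueError(f"no training samples for class(es): {missing}")
    if not classes:
        raise ValueError("training set is empty")
    centers: dict[TissueClass, np.ndarray] = {}
    for tc in classes:
        Xc = X[y == int(tc)]
        if n_centers is not None and Xc.shape[0] > n_centers:
            prototypes, _ = kmeans2(Xc, n_centers, minit="++", seed=seed)
            centers[tc] = prototypes
        else:
            centers[tc] = Xc.copy()
    M = len(classes)
    weights = np.zeros((M, M))
    for j, tc in enumerate(classes):
        weights[j, j] = 1.0 / centers[tc].shape[0]
    return PNNModel(
        classes=classes,
        centers=centers,
        sigma=float(sigma),
        weights=weights,
        feature_dim=X.shape[1],
    )


def pattern_layer(model: PNNModel, x: np.ndarray) -> np.ndarray:
    """Per-class summed kernel responses H_k(x).

    Accepts a single vector (returns shape (M,)) or a matrix of rows
    (returns (n, M)).
    """
    single = np.asarray(x).ndim == 1
    X = _check_input(model, x)
    H = np.empty((X.shape[0], len(model.classes)))
    for k, tc in enumerate(model.classes):
        C = model.centers[tc]
        sq = np.sum((X[:, None, :] - C[None, :, :]) ** 2, axis=2)
        H[:, k] = np.exp(-sq / (2.0 * model.sigma**2)).sum(axis=1)
    return H[0] if single else H


def pnn_output(model: PNNModel, x: np.ndarray) -> np.ndarray:
    """Summation-layer scores Y_j = sum_k w_jk H_k(x)."""
    H = pattern_layer(model, x)
    return H @ model.weights.T


def pnn_predict(model: PNNModel, x: np.ndarray) -> TissueClass | list[TissueClass]:
    """Argmax class decision; exact ties go to the lowest class ordinal."""
    single = np.asarray(x).ndim == 1
    Y = np.atleast_2d(pnn_output(model, x))
    idx = np.argmax(Y, axis=1)  # first max wins; classes are ordinal-sorted
    preds = [model.classes[i] for i in idx]
    return preds[0] if single else preds


def loo_error_rate(features: list[FeatureVector], sigma: float) -> float:
    """Leave-one-out misclassification rate of the exemplar PNN at ``sigma``.

    Each sample is scored against the model trained on the remaining
    samples; with default weights that is the class-average kernel
    response with the sample's own kernel removed and its class count
    reduced by one.
    """
    X, labels = feature_matrix(features)
    if any(lab is None for lab in labels):
        raise ValueError("all samples must carry a label")
    y = np.array([int(lab) for lab in labels])
    classes = [tc for tc in CLASS_ORDER if int(tc) in set(y)]
    for tc in classes:
        if np.sum(y == int(tc)) < 2:
            raise ValueError(f"class {tc.label} needs >= 2 samples for leave-one-out")
    sq = np.sum((X[:, None, :] - X[None, :, :]) ** 2, axis=2)
    K = np.exp(-sq / (2.0 * sigma**2))
    np.fill_diagonal(K, 0.0)
    n = X.shape[0]
    scores = np.empty((n, len(classes)))
    for k, tc in enumerate(classes):
        mask = y == int(tc)
        n_k = mask.sum()
        denom = np.where(mask, n_k - 1, n_k)  # own class loses the held-out exemplar
        scores[:, k] = K[:, mask].sum(axis=1) / denom
    pred = np.array([int(classes[i]) for i in np.argmax(scores, axis=1)])
    return float(np.mean(pred != y))


def select_sigma(
    features: list[FeatureVector],
    grid: np.ndarray,
    error_goal: float = 0.01,
) -> float:
    """Pick a smoothing width by ascending leave-one-out grid search.

    Returns the first (smallest) grid value whose LOO misclassification
    rate is <= ``error_goal``; if none attains the goal, the grid value
    with the smallest LOO rate (ties toward smaller sigma).  Deterministic.
    """
    grid = np.sort(np.asarray(grid, dtype=float))
    if grid.size == 0 or np.any(grid <= 0):
        raise ValueError("sigma grid must be nonempty and strictly positive")
    best_sigma, best_rate = None, np.inf
    for sigma in grid:
        rate = loo_error_rate(features, float(sigma))
        if rate <= error_goal:
            return float(sigma)
        if rate < best_rate:
            best_sigma, best_rate = float(sigma), rate
    return best_sigma


def model_to_json(model: PNNModel, path: str | Path | None = None) -> str:
    """Serialize a model to a JSON document (optionally writing it out)."""
    doc = {
        "format": "irpnn-pnn-model",
        "version": 1,
        "classes": [tc.label for tc in model.classes],
        "sigma": model.sigma,
        "feature_dim": model.feature_dim,
        "weights": model.weights.tolist(),
        "centers": {tc.label: model.centers[tc].tolist() for tc in model.classes},
    }
    text = json.dumps(doc, indent=2)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


def model_from_json(source: str | Path) -> PNNModel:
    """Load a model written by :func:`model_to_json`."""
    p = Path(source)
    text = p.read_text() if p.exists() else str(source)
    doc = json.loads(text)
    if doc.get("format") != "irpnn-pnn-model":
        raise ValueError("not a PNN model document")
    classes = [TissueClass.from_label(lab) for lab in doc["classes"]]
    return PNNModel(
        classes=classes,
        centers={tc: np.array(doc["centers"][tc.label], dtype=float) for tc in classes},
        sigma=float(doc["sigma"]),
        weights=np.array(doc["weights"], dtype=float),
        feature_dim=int(doc["feature_dim"]),
    )
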