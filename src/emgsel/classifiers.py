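"""Gaussian discriminant classifiers (LDA / QDA) and the error metric.

Both discriminants model each class as a multivariate Gaussian with
empirical priors; LDA pools the within-class covariance (linear decision
boundaries), QDA estimates one covariance per class (quadratic boundaries,
hence many more parameters and a larger appetite for training data).  When
a covariance is numerically singular it is shrunk toward a scaled identity,
with the shrinkage weight escalated from 0 in steps of 1e-4 until the
matrix admits a Cholesky factorisation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_triangular

__all__ = [
    "DiscriminantModel",
    "fit_discriminant",
    "predict",
    "classification_error",
]


def _regularize(cov: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Return (cov, cholesky factor, shrinkage) with shrinkage escalated
    additively by 1e-4 until the covariance is positive-definite."""
    d = cov.shape[0]
    scale = max(float(np.trace(cov)) / d, 1e-12)
    target = scale * np.eye(d)
    w = 0.0
    while w <= 1.0:
        reg = (1.0 - w) * cov + w * target
        try:
            chol = np.linalg.cholesky(reg)
            return reg, chol, w
        except np.linalg.LinAlgError:
            w = w + 1e-4 if w > 0 else 1e-4
    raise np.linalg.LinAlgError("covariance could not be regularized")


@dataclass
class DiscriminantModel:
    """Fitted Gaussian discriminant.

    ``covariances`` holds one matrix for QDA and a single shared (pooled)
    matrix replicated per class for LDA, so prediction code is uniform.
    """

    kind: str  # "LDA" | "QDA"
    classes: np.ndarray
    priors: np.ndarray
    means: np.ndarray  # (K, d)
    covariances: np.ndarray  # (K, d, d)
    shrinkage: np.ndarray  # (K,) shrinkage weight actually applied

    def __post_init__(self) -> None:
        if not np.isclose(self.priors.sum(), 1.0):
            raise ValueError("priors must sum to 1")

    @property
    def n_features(self) -> int:
        return self.means.shape[1]

    def log_scores(self, X: np.ndarray) -> np.ndarray:
        """Per-class Gaussian log posterior scores (up to a shared constant)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"model expects {self.n_features} features, got {X.shape[1]}"
            )
        scores = np.empty((X.shape[0], len(self.classes)))
        for k in range(len(self.classes)):
            chol = np.linalg.cholesky(self.covariances[k])
            diff = X - self.means[k]
            sol = solve_triangular(chol, diff.T, lower=True)
            maha = np.sum(sol**2, axis=0)
            logdet = 2.0 * np.sum(np.log(np.diag(chol)))
            scores[:, k] = -0.5 * maha - 0.5 * logdet + np.log(self.priors[k])
        return scores


def fit_discriminant(kind: str, X, y) -> DiscriminantModel:
    """Fit an LDA or QDA to labelled rows.

    Class covariances use the unbiased within-class estimate; the pooled
    LDA covariance divides by (N - K).
    """
    kind = kind.upper()
    if kind not in ("LDA", "QDA"):
        raise ValueError(f"kind must be 'LDA' or 'QDA', got {kind!r}")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y)
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y must have equal row counts")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes to fit a discriminant")
    n, d = X.shape
    K = len(classes)
    means = np.empty((K, d))
    priors = np.empty(K)
    scatters = []
    counts = []
    for k, c in enumerate(classes):
        rows = X[y == c]
        if rows.shape[0] < 2:
            raise ValueError(f"class {c!r} has fewer than 2 rows")
        means[k] = rows.mean(axis=0)
        priors[k] = rows.shape[0] / n
        diff = rows - means[k]
        scatters.append(diff.T @ diff)
        counts.append(rows.shape[0])
    covs = np.empty((K, d, d))
    shrink = np.empty(K)
    if kind == "LDA":
        pooled = sum(scatters) / (n - K)
        reg, _, w = _regularize(pooled)
        covs[:] = reg
        shrink[:] = w
    else:
        for k in range(K):
            covk = scatters[k] / (counts[k] - 1)
            covs[k], _, shrink[k] = _regularize(covk)
    return DiscriminantModel(
        kind=kind,
        classes=classes,
        priors=priors,
        means=means,
        covariances=covs,
        shrinkage=shrink,
    )


def predict(model, X) -> np.ndarray:
    """Class labels by maximum score; ties go to the lowest class index."""
    scores = model.log_scores(np.atleast_2d(np.asarray(X, dtype=float)))
    return np.asarray(model.classes)[np.argmax(scores, axis=1)]


def classification_error(predicted, truth) -> float:
    """Fraction of mismatched labels."""
    p = np.asarray(predicted)
    t = np.asarray(truth)
    if p.shape != t.shape:
        raise ValueError("predicted and truth must have equal length")
    if p.size == 0:
        raise ValueError("empty label vectors")
    return float(np.mean(p != t))
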