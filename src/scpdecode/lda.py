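"""Multiclass linear discriminant analysis with pooled covariance.

Each class y is modeled as Gaussian with its own mean μ_y and one shared
covariance Σ; the posterior follows Bayes' rule,

    P(C=y | x) ∝ P(C=y) · N(x; μ_y, Σ),

and classification takes the argmax over classes.  Σ is the pooled
within-class covariance, optionally shrunk toward a scaled identity,
(1−s)·Σ̂ + s·(tr Σ̂ / p)·I.  Posteriors are computed in log space through
a Cholesky factorization of Σ (no explicit inverse) with log-sum-exp
normalization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve

logger = logging.getLogger(__name__)


@dataclass
class LDAModel:
    class_labels: np.ndarray     # fixed (sorted) order; prediction ties break here
    means: np.ndarray            # n_classes × p
    pooled_cov: np.ndarray       # p × p, after shrinkage
    priors: np.ndarray           # sums to 1
    shrinkage: float

    @property
    def dim(self) -> int:
        return self.means.shape[1]


def fit_lda(X: np.ndarray, y: np.ndarray, shrinkage: float = 0.05,
            priors: str = "empirical") -> LDAModel:
    """Fit class means, pooled within-class covariance and priors.

    ``priors="empirical"`` uses class frequencies; ``"uniform"`` uses 1/K.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if X.ndim != 2:
        raise ValueError("X must be trials × features")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite features")
    if not 0 <= shrinkage <= 1:
        raise ValueError("shrinkage must be in [0, 1]")
    classes = np.unique(y)
    n, p = X.shape
    means = np.empty((len(classes), p))
    pooled = np.zeros((p, p))
    counts = np.empty(len(classes))
    for k, cls in enumerate(classes):
        Xc = X[y == cls]
        if len(Xc) < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 trials")
        counts[k] = len(Xc)
        means[k] = Xc.mean(axis=0)
        R = Xc - means[k]
        pooled += R.T @ R
    pooled /= n - len(classes)
    if shrinkage > 0:
        pooled = (1 - shrinkage) * pooled + shrinkage * (
            np.trace(pooled) / p) * np.eye(p)
    pooled = 0.5 * (pooled + pooled.T)
    if np.trace(pooled) <= 0:
        logger.warning("degenerate (zero) pooled covariance; using identity — "
                       "posteriors will equal the priors")
        pooled = np.eye(p)
    if priors == "empirical":
        pri = counts / n
    elif priors == "uniform":
        pri = np.full(len(classes), 1.0 / len(classes))
    else:
        raise ValueError(f"unknown priors mode {priors!r}")
    return LDAModel(class_labels=classes, means=means, pooled_cov=pooled,
                    priors=pri, shrinkage=shrinkage)


def _log_posteriors(model: LDAModel, X: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    if X.shape[1] != model.dim:
        raise ValueError(f"expected {model.dim} features, got {X.shape[1]}")
    try:
        factor = cho_factor(model.pooled_cov, lower=True)
    except np.linalg.LinAlgError as exc:
        raise ValueError("pooled covariance not positive definite; "
                         "increase shrinkage") from exc
    logp = np.empty((X.shape[0], len(model.class_labels)))
    for k in range(len(model.class_labels)):
        d = X - model.means[k]
        maha = np.einsum("ij,ji->i", d, cho_solve(factor, d.T))
        logp[:, k] = np.log(model.priors[k]) - 0.5 * maha
    logp -= logp.max(axis=1, keepdims=True)
    logp -= np.log(np.exp(logp).sum(axis=1, keepdims=True))
    return logp


def posterior(model: LDAModel, x: np.ndarray) -> np.ndarray:
    """Class posteriors for one sample (or trials × p, row-wise)."""
    x = np.asarray(x, dtype=np.float64)
    post = np.exp(_log_posteriors(model, x))
    return post[0] if x.ndim == 1 else post


def predict(model: LDAModel, X: np.ndarray) -> np.ndarray:
    """Argmax-posterior labels; ties break toward the earlier class label."""
    logp = _log_posteriors(model, np.atleast_2d(X))
    return model.class_labels[np.argmax(logp, axis=1)]


def confusion_matrix(y_true: Sequence, y_pred: Sequence,
                     classes: Sequence) -> np.ndarray:
    """Counts with rows = actual class, columns = predicted class."""
    classes = list(classes)
    cm = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        cm[classes.index(t), classes.index(p)] += 1
    return cm


def save_lda(model: LDAModel, path, provenance: Optional[dict] = None) -> None:
    """Serialize a fitted model to the internal HDF5 container.

    ``provenance`` (window endpoint, selected channels, ...) is stored as
    JSON in a root attribute.
    """
    import json

    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["model_version"] = 1
        f.attrs["shrinkage"] = model.shrinkage
        if provenance:
            f.attrs["provenance"] = json.dumps(provenance)
        f.create_dataset("class_labels",
                         data=np.array([str(c) for c in model.class_labels],
                                       dtype=h5py.string_dtype()),
                         track_times=False)
        for name in ("means", "pooled_cov", "priors"):
            f.create_dataset(name, data=getattr(model, name),
                             track_times=False)


def load_lda(path) -> LDAModel:
    import h5py

    with h5py.File(path, "r") as f:
        if int(f.attrs.get("model_version", -1)) != 1:
            raise ValueError("unsupported model container version")
        return LDAModel(
            class_labels=np.array([s.decode() for s in f["class_labels"][()]],
                                  dtype=object),
            means=f["means"][()],
            pooled_cov=f["pooled_cov"][()],
            priors=f["priors"][()],
            shrinkage=float(f.attrs["shrinkage"]),
        )
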