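"""Canonical variate analysis (multi-class Fisher discriminant) for
channel selection.

For a trials × features matrix with K class labels, CVA solves the
generalized eigenproblem B·v = λ·W·v, where B is the between-class and W
the within-class scatter matrix; at most K−1 eigenvalues are nonzero.
Each feature j gets a discriminant power (DP)

    dp_j = Σ_k λ_k · w_jk²   (normalized to sum to 1),

with w the W-normalized eigenvectors (vᵀWv = 1, as returned by a
generalized symmetric eigensolver).  Channel DP sums dp over the
channel's columns; channels are ranked by DP and the top n kept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import linalg

logger = logging.getLogger(__name__)


@dataclass
class CVAResult:
    eigenvalues: np.ndarray            # descending, length ≤ K−1
    weights: np.ndarray                # features × canonical functions
    dp_per_feature: np.ndarray         # sums to 1
    dp_per_channel: Dict[str, float]   # sums to 1
    ranking: List[str]                 # channel names, descending DP
    selected: List[str]                # top n_select names


def class_scatter(X: np.ndarray, y: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Between-class (B) and within-class (W) scatter matrices."""
    X = np.asarray(X, dtype=np.float64)
    grand = X.mean(axis=0)
    p = X.shape[1]
    B = np.zeros((p, p))
    W = np.zeros((p, p))
    for cls in np.unique(y):
        Xc = X[y == cls]
        if len(Xc) < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 trials")
        mc = Xc.mean(axis=0)
        d = mc - grand
        B += len(Xc) * np.outer(d, d)
        R = Xc - mc
        W += R.T @ R
    return B, W


def _regularize(W: np.ndarray, eps: float = 1e-6,
                max_cond: float = 1e10) -> np.ndarray:
    """Ridge W toward scaled identity only when ill-conditioned, ×10 escalation."""
    p = W.shape[0]
    if np.linalg.cond(W) < max_cond:
        return W
    scale = np.trace(W) / p
    if scale <= 0:
        scale = 1.0
    while True:
        Wr = W + eps * scale * np.eye(p)
        cond = np.linalg.cond(Wr)
        if cond < max_cond or eps > 1e2:
            break
        logger.info("within-class scatter ill-conditioned (cond=%.2e); "
                    "escalating ridge to %.0e", cond, eps * 10)
        eps *= 10
    return Wr


def standardize_fit(X: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Per-column mean and standard deviation (zero-variance guard → 1)."""
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    return mu, sd


def fit_cva(X: np.ndarray, y: np.ndarray,
            provenance: Sequence[Tuple[str, float]],
            n_select: int = 10, standardize: bool = True,
            channel_mode: str = "stacked", dp_mode: str = "coefficients",
            channel_order: Optional[Sequence[str]] = None) -> CVAResult:
    """Rank channels by discriminant power from a window's feature matrix.

    ``channel_mode="stacked"`` (default) runs CVA on the full channels ×
    time-points matrix and sums DP over each channel's columns;
    ``"mean"`` first averages each channel's columns and runs CVA on the
    per-channel means.  ``dp_mode="coefficients"`` (default) credits
    features by their squared W-normalized eigenvector coefficients;
    ``"structure"`` uses squared structure coefficients (feature ↔
    canonical-variate correlations), which is insensitive to the
    coefficient inflation that near-collinear feature blocks cause.
    Ties in channel DP break by ``channel_order`` (default: first
    appearance in provenance).
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if len(provenance) != X.shape[1]:
        raise ValueError("provenance length must match feature count")
    chan_of_col = [name for name, _t in provenance]
    if channel_order is None:
        channel_order = list(dict.fromkeys(chan_of_col))
    if n_select > len(channel_order):
        raise ValueError("n_select exceeds number of channels")

    if channel_mode == "mean":
        cols = {c: [j for j, n in enumerate(chan_of_col) if n == c]
                for c in channel_order}
        X = np.column_stack([X[:, cols[c]].mean(axis=1) for c in channel_order])
        chan_of_col = list(channel_order)
    elif channel_mode != "stacked":
        raise ValueError(f"unknown channel_mode {channel_mode!r}")

    if standardize:
        mu, sd = standardize_fit(X)
        X = (X - mu) / sd

    B, W = class_scatter(X, y)
    Wr = _regularize(W)
    n_cf = len(np.unique(y)) - 1
    evals, evecs = linalg.eigh(B, Wr)
    order = np.argsort(evals)[::-1][:n_cf]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]

    if dp_mode == "coefficients":
        dp_raw = (evecs**2 * evals[np.newaxis, :]).sum(axis=1)
    elif dp_mode == "structure":
        scores = X @ evecs                      # canonical variates
        sx = X.std(axis=0, ddof=0)
        ss = scores.std(axis=0, ddof=0)
        centered = X - X.mean(axis=0)
        cov = centered.T @ (scores - scores.mean(axis=0)) / X.shape[0]
        denom = np.outer(np.where(sx > 0, sx, 1.0), np.where(ss > 0, ss, 1.0))
        corr = cov / denom
        dp_raw = (corr**2 * evals[np.newaxis, :]).sum(axis=1)
    else:
        raise ValueError(f"unknown dp_mode {dp_mode!r}")
    total = dp_raw.sum()
    dp_feature = dp_raw / total if total > 0 else np.full_like(dp_raw,
                                                               1.0 / len(dp_raw))
    dp_channel = {c: 0.0 for c in channel_order}
    for j, c in enumerate(chan_of_col):
        dp_channel[c] += dp_feature[j]

    chan_idx = {c: i for i, c in enumerate(channel_order)}
    ranking = sorted(dp_channel, key=lambda c: (-dp_channel[c], chan_idx[c]))
    return CVAResult(
        eigenvalues=evals,
        weights=evecs,
        dp_per_feature=dp_feature,
        dp_per_channel=dp_channel,
        ranking=ranking,
        selected=ranking[:n_select],
    )


def select_top_channels(result: CVAResult, n: int) -> List[str]:
    """First ``n`` channels of the DP ranking (deterministic tie order)."""
    if n > len(result.ranking):
        raise ValueError("n exceeds number of ranked channels")
    return result.ranking[:n]
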