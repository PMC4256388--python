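"""Per-class dictionary learning on sub-volume samples.

Each activity class gets its own K-word dictionary learned by
reconstruction ICA (RICA): an unconstrained smooth objective

    f(W) = (1/N) sum_i ||W^T W x_i - x_i||^2
         + (lambda/N) sum_i sum_k log cosh(w_k . x_i)

whose first term keeps ``W^T W`` close to an identity on the data
(allowing over-complete ``K > p``) and whose second, smooth-L1 term
makes the responses ``W x`` sparse.  The objective and its analytic
gradient are exposed separately so the solver (limited-memory
quasi-Newton) stays a plain library call.  RICA behaves best on
approximately whitened inputs, so a PCA whitener fitted on the pooled
training samples is part of the model and is reused verbatim at coding
time.  A seeded k-means clustering of the same samples provides the
baseline vocabulary; its centroids are a drop-in replacement for the
RICA words.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize
from sklearn.cluster import KMeans

from .errors import ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "Whitener",
    "Dictionary",
    "Codebook",
    "fit_whitener",
    "rica_objective",
    "learn_dictionary",
    "kmeans_dictionary",
    "pool_codebook",
]

#: tag describing the pinned sub-volume vectorization order; serialized
#: with the model so training and prediction can never disagree.
VECTORIZATION_LAYOUT = "frame-fastest,then-joint,then-coordinate"


@dataclass
class Whitener:
    """Affine PCA-whitening transform ``z = A (x - mean)``."""

    mean: np.ndarray  # (p,)
    transform: np.ndarray  # (p, p)
    eps: float

    def apply(self, x: np.ndarray) -> np.ndarray:
        """Whiten a ``(p,)`` vector or ``(p, N)`` sample matrix."""
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 1:
            return self.transform @ (x - self.mean)
        return self.transform @ (x - self.mean[:, None])


@dataclass
class Dictionary:
    """K learned words (rows) for one activity class."""

    words: np.ndarray  # (K, p)
    activity_label: Optional[str] = None
    lam: float = 0.5
    trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    converged: bool = True
    method: str = "rica"

    @property
    def n_words(self) -> int:
        return self.words.shape[0]

    @property
    def sample_dim(self) -> int:
        return self.words.shape[1]


@dataclass
class Codebook:
    """All per-class dictionaries stacked into one ``(K*A, p)`` matrix."""

    words: np.ndarray
    class_slices: dict[str, tuple[int, int]]
    whitener: Whitener
    layout: str = VECTORIZATION_LAYOUT

    @property
    def n_words(self) -> int:
        return self.words.shape[0]

    @property
    def sample_dim(self) -> int:
        return self.words.shape[1]

    @property
    def classes(self) -> list[str]:
        return list(self.class_slices)


def fit_whitener(x: np.ndarray, eps: float = 1e-5) -> Whitener:
    """Fit a full-rank PCA whitener to a ``(p, N)`` sample matrix.

    Eigenvectors of the sample covariance rotate to principal axes and
    each axis is scaled by ``1/sqrt(eigenvalue + eps)``; ``eps``
    regularizes directions with near-zero variance and keeps the
    transform invertible.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 2:
        raise ValidationError(f"expected (p, N) matrix, got shape {x.shape}")
    if x.shape[1] < 2:
        raise ValidationError("need at least 2 samples to fit a whitener")
    mean = x.mean(axis=1)
    centered = x - mean[:, None]
    cov = centered @ centered.T / x.shape[1]
    eigval, eigvec = np.linalg.eigh(cov)
    eigval = np.clip(eigval, 0.0, None)
    transform = (eigvec / np.sqrt(eigval + eps)) @ eigvec.T
    return Whitener(mean=mean, transform=transform, eps=eps)


def rica_objective(
    w: np.ndarray, x: np.ndarray, lam: float
) -> tuple[float, np.ndarray]:
    """Value and analytic gradient of the RICA objective at ``W``.

    Parameters
    ----------
    w:
        ``(K, p)`` dictionary; rows are words.
    x:
        ``(p, N)`` sample matrix (ideally whitened).
    lam:
        Non-negative weight of the log-cosh sparsity penalty.
    """
    w = np.asarray(w, dtype=np.float64)
    x = np.asarray(x, dtype=np.float64)
    if w.ndim != 2 or x.ndim != 2 or w.shape[1] != x.shape[0]:
        raise ValidationError(
            f"shape mismatch: W {w.shape} vs X {x.shape} (need W:(K,p), X:(p,N))"
        )
    if lam < 0:
        raise ValidationError("lambda must be non-negative")
    n = x.shape[1]
    wx = w @ x  # (K, N)
    residual = w.T @ wx - x  # (p, N)
    value = float(np.sum(residual * residual)) / n
    grad = (2.0 / n) * (wx @ residual.T + w @ residual @ x.T)
    if lam > 0:
        # log cosh computed stably via |u| + log1p(exp(-2|u|)) - log 2
        au = np.abs(wx)
        value += lam / n * float(np.sum(au + np.log1p(np.exp(-2.0 * au)) - np.log(2.0)))
        grad += (lam / n) * (np.tanh(wx) @ x.T)
    return value, grad


def _init_words(k: int, p: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    w = rng.standard_normal((k, p)) / np.sqrt(p)
    return w / np.linalg.norm(w, axis=1, keepdims=True)


def learn_dictionary(
    x: np.ndarray,
    k: int,
    lam: float = 0.5,
    *,
    seed: int = 0,
    max_iter: int = 200,
    gtol: float = 1e-6,
    activity_label: Optional[str] = None,
) -> Dictionary:
    """Learn a K-word RICA dictionary from (whitened) samples ``x``.

    Minimizes :func:`rica_objective` with L-BFGS-B from a seeded random
    initialization (normal rows scaled by ``1/sqrt(p)`` and normalized).
    The per-iterate objective trace is recorded; ``converged`` reflects
    the solver's gradient-tolerance status at up to ``max_iter``
    iterations.
    """
    x = np.asarray(x, dtype=np.float64)
    p, n = x.shape
    if n < k:
        warnings.warn(
            f"learning {k} words from only {n} samples; dictionary may overfit",
            stacklevel=2,
        )
    w0 = _init_words(k, p, seed)
    trace: list[float] = [rica_objective(w0, x, lam)[0]]

    def fun(flat: np.ndarray) -> tuple[float, np.ndarray]:
        value, grad = rica_objective(flat.reshape(k, p), x, lam)
        if not np.isfinite(value):
            raise FloatingPointError(
                f"RICA objective became non-finite (lambda={lam}, K={k}, p={p})"
            )
        return value, grad.ravel()

    def callback(flat: np.ndarray) -> None:
        trace.append(rica_objective(flat.reshape(k, p), x, lam)[0])

    result = minimize(
        fun,
        w0.ravel(),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "gtol": gtol, "ftol": 1e-12},
        callback=callback,
    )
    words = result.x.reshape(k, p)
    logger.info(
        "RICA dictionary '%s': K=%d p=%d N=%d, objective %.6g -> %.6g in %d iterations",
        activity_label, k, p, n, trace[0], result.fun, result.nit,
    )
    return Dictionary(
        words=words,
        activity_label=activity_label,
        lam=lam,
        trace=np.asarray(trace),
        converged=bool(result.success or result.nit >= max_iter),
        method="rica",
    )


def kmeans_dictionary(
    x: np.ndarray,
    k: int,
    *,
    seed: int = 0,
    activity_label: Optional[str] = None,
    n_init: int = 10,
) -> Dictionary:
    """Baseline vocabulary: seeded k-means centroids as dictionary words."""
    x = np.asarray(x, dtype=np.float64)
    p, n = x.shape
    if k > n:
        raise ValidationError(f"cannot form {k} clusters from {n} samples")
    km = KMeans(n_clusters=k, random_state=seed, n_init=n_init)
    km.fit(x.T)
    return Dictionary(
        words=km.cluster_centers_.copy(),
        activity_label=activity_label,
        lam=0.0,
        trace=np.array([km.inertia_]),
        converged=True,
        method="kmeans",
    )


def pool_codebook(dicts: Sequence[Dictionary], whitener: Whitener) -> Codebook:
    """Stack per-class dictionaries (in class-label order) into a codebook.

    The pooled vocabulary is intended to be over-complete (more words
    than sub-volume dimensions); a warning is emitted when it is not.
    """
    if not dicts:
        raise ValidationError("no dictionaries to pool")
    labels = [d.activity_label for d in dicts]
    if any(lbl is None for lbl in labels):
        raise ValidationError("every dictionary needs an activity_label to be pooled")
    if len(set(labels)) != len(labels):
        raise ValidationError(f"duplicate activity labels in {labels}")
    dims = {d.sample_dim for d in dicts}
    if len(dims) != 1:
        raise ValidationError(f"dictionaries disagree on sample dimension: {dims}")
    ordered = sorted(dicts, key=lambda d: d.activity_label)
    slices: dict[str, tuple[int, int]] = {}
    row = 0
    blocks = []
    for d in ordered:
        slices[d.activity_label] = (row, row + d.n_words)
        blocks.append(d.words)
        row += d.n_words
    words = np.vstack(blocks)
    p = words.shape[1]
    if words.shape[0] <= p:
        warnings.warn(
            f"codebook has {words.shape[0]} words for dimension {p}; "
            "not over-complete",
            stacklevel=2,
        )
    return Codebook(words=words, class_slices=slices, whitener=whitener)
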