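"""Fast approximate sparse coding and per-video sparse histograms.

Instead of solving an L1 sparse-coding problem per sub-volume, a sample
is whitened and projected onto the codebook with one matrix-vector
product; only the L largest-magnitude coefficients are kept (the rest
are zeroed).  Counting, for every codebook word, how many of a video's
sub-volumes kept a nonzero coefficient on that word yields the video's
sparse histogram — the fixed-length feature handed to the classifier.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .dictionary_learning import Codebook
from .errors import ValidationError

__all__ = [
    "SparseCode",
    "ActivityHistogram",
    "project",
    "project_samples",
    "top_l_sparsify",
    "encode_samples",
    "video_histogram",
    "sparsity_degree",
]


@dataclass
class SparseCode:
    """Nonzero kept coefficients of one sub-volume sample."""

    indices: np.ndarray  # strictly increasing word indices
    values: np.ndarray  # matching coefficients (all nonzero)
    total_dim: int

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.indices.shape != self.values.shape:
            raise ValidationError("indices and values must have equal length")
        if self.indices.size and (
            np.any(np.diff(self.indices) <= 0)
            or self.indices[0] < 0
            or self.indices[-1] >= self.total_dim
        ):
            raise ValidationError("indices must be strictly increasing and in range")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("coefficients must be finite")


@dataclass
class ActivityHistogram:
    """Per-video word-occurrence histogram over the pooled codebook."""

    bins: np.ndarray  # (K*A,) non-negative
    n_samples: int
    normalized: bool

    def __post_init__(self) -> None:
        self.bins = np.asarray(self.bins, dtype=np.float64)
        if np.any(self.bins < 0):
            raise ValidationError("histogram bins must be non-negative")


def project(codebook: Codebook, x: np.ndarray) -> np.ndarray:
    """Project one raw sample onto the codebook: ``alpha = B whiten(x)``."""
    x = np.asarray(x, dtype=np.float64)
    if x.shape != (codebook.sample_dim,):
        raise ValidationError(
            f"sample has shape {x.shape}, codebook expects ({codebook.sample_dim},)"
        )
    return codebook.words @ codebook.whitener.apply(x)


def project_samples(codebook: Codebook, x: np.ndarray) -> np.ndarray:
    """Vectorized :func:`project` for a ``(p, N)`` sample matrix."""
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 2 or x.shape[0] != codebook.sample_dim:
        raise ValidationError(
            f"sample matrix has shape {x.shape}, codebook expects "
            f"({codebook.sample_dim}, N)"
        )
    return codebook.words @ codebook.whitener.apply(x)


def top_l_sparsify(alpha: np.ndarray, l_keep: int) -> SparseCode:
    """Keep the ``l_keep`` largest-magnitude coefficients of ``alpha``.

    Ties at the threshold magnitude keep the lower index (stable order);
    kept entries that are exactly zero are pruned — they are not
    occurrences of a word.  ``l_keep >= len(alpha)`` keeps every nonzero
    entry.
    """
    if l_keep < 1:
        raise ValidationError("L must be at least 1")
    alpha = np.asarray(alpha, dtype=np.float64).ravel()
    dim = alpha.size
    order = np.argsort(-np.abs(alpha), kind="stable")
    kept = order[: min(l_keep, dim)]
    kept = kept[alpha[kept] != 0.0]
    kept.sort()
    return SparseCode(indices=kept, values=alpha[kept], total_dim=dim)


def encode_samples(codebook: Codebook, x: np.ndarray, l_keep: int) -> list[SparseCode]:
    """Project every column of ``x`` and sparsify each projection."""
    alphas = project_samples(codebook, x)
    return [top_l_sparsify(alphas[:, i], l_keep) for i in range(alphas.shape[1])]


def video_histogram(
    codes: Sequence[SparseCode], total_dim: int, normalize: bool = True
) -> ActivityHistogram:
    """Count nonzero-coefficient occurrences per word over a video's codes.

    With ``normalize`` the counts are divided by their grand total, so
    the bins sum to 1 and videos of different lengths are comparable.
    """
    if not codes:
        raise ValidationError("video produced no samples (empty code list)")
    if any(c.total_dim != total_dim for c in codes):
        raise ValidationError("all codes must share total_dim with the histogram")
    counts = np.zeros(total_dim)
    all_idx = np.concatenate([c.indices for c in codes]) if codes else np.empty(0)
    if all_idx.size:
        counts = np.bincount(all_idx, minlength=total_dim).astype(np.float64)
    if normalize:
        total = counts.sum()
        if total > 0:
            counts = counts / total
    return ActivityHistogram(bins=counts, n_samples=len(codes), normalized=normalize)


def sparsity_degree(hist: ActivityHistogram | np.ndarray) -> float:
    """Fraction of histogram bins that are nonzero (in [0, 1])."""
    bins = hist.bins if isinstance(hist, ActivityHistogram) else np.asarray(hist)
    if bins.size == 0:
        raise ValidationError("histogram has no bins")
    return float(np.count_nonzero(bins)) / bins.size
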