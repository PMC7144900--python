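"""Correlation transform, PCA and per-PC-count Euclidean distance matrices."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .errors import MatrixValidationError, ParameterError
from .hic_io import ContactMatrix

__all__ = [
    "PCEmbedding",
    "pearson_transform",
    "pca_reduce",
    "euclidean_distance_matrix",
]

DEFAULT_N_PC_MAX = 200


@dataclass(frozen=True)
class PCEmbedding:
    """Principal-component coordinates of the correlation-matrix rows.

    ``scores`` has one row per (kept) bin and one column per retained
    component, ordered by decreasing variance; ``explained_variance`` holds
    per-component fractions of the total variance (all components, so the
    retained cumulative sum may be < 1).
    """

    scores: np.ndarray
    explained_variance: np.ndarray
    n_pc_max: int

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def _as_values(m) -> np.ndarray:
    return m.values if isinstance(m, ContactMatrix) else np.asarray(m, dtype=float)


def pearson_transform(m) -> np.ndarray:
    """Pearson correlation-coefficient matrix of the columns of ``m``.

    Accepts a :class:`~tadpole.hic_io.ContactMatrix` (already filtered) or a
    plain array.  Entry ``(i, j)`` is the correlation of columns ``i`` and
    ``j``; the diagonal is exactly 1.
    """
    x = _as_values(m)
    if x.shape[0] < 4:
        raise MatrixValidationError("pearson_transform needs at least 4 bins")
    sd = x.std(axis=0)
    zero_var = np.flatnonzero(sd == 0)
    if zero_var.size:
        raise MatrixValidationError(
            f"zero-variance columns {zero_var.tolist()}; mask them before transforming"
        )
    pcc = np.corrcoef(x, rowvar=False)
    np.clip(pcc, -1.0, 1.0, out=pcc)
    np.fill_diagonal(pcc, 1.0)
    return pcc


def pca_reduce(pcc: np.ndarray, n_pc_max: int = DEFAULT_N_PC_MAX) -> PCEmbedding:
    """PCA of ``pcc`` rows (observations), columns mean-centered, no scaling.

    Components beyond the numerical rank are discarded, then the count is
    clamped to ``n_pc_max``.
    """
    x = np.asarray(pcc, dtype=float)
    if np.any(~np.isfinite(x)):
        raise MatrixValidationError("pca_reduce: non-finite entries in input")
    if n_pc_max < 1:
        raise ParameterError(f"n_pc_max must be >= 1, got {n_pc_max}")
    centered = x - x.mean(axis=0, keepdims=True)
    u, s, _vt = np.linalg.svd(centered, full_matrices=False)
    # numerical rank: mirror numpy.linalg.matrix_rank's default cutoff
    tol = s[0] * max(centered.shape) * np.finfo(float).eps if s.size else 0.0
    rank = int(np.sum(s > tol))
    k = min(n_pc_max, max(rank, 1))
    total_var = float(np.sum(s**2))
    frac = (s**2 / total_var) if total_var > 0 else np.zeros_like(s)
    scores = u[:, :k] * s[:k]
    return PCEmbedding(scores=scores, explained_variance=frac[:k], n_pc_max=n_pc_max)


def euclidean_distance_matrix(e: PCEmbedding, n_pc: int) -> np.ndarray:
    """Pairwise Euclidean distances between rows of the first ``n_pc`` scores."""
    if not 1 <= n_pc <= e.n_components:
        raise ParameterError(
            f"n_pc must be in [1, {e.n_components}], got {n_pc}"
        )
    return squareform(pdist(e.scores[:, :n_pc], metric="euclidean"))
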