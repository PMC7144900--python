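"""Constrained incremental sum-of-squares (CONISS) hierarchical clustering.

Agglomerative clustering in which only genomically adjacent clusters may
merge.  The dispersion of a cluster C is defined from squared pairwise
distances as ``sum_{i<j in C} d_ij^2 / |C|`` and the cost of a merge is the
increase in total within-cluster dispersion.  Merge costs are maintained
with the Lance-Williams recurrence for incremental sum of squares, which is
exact for this dispersion (validated against a from-scratch oracle in the
test suite).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import MatrixValidationError, ParameterError
from .partition import Partition

__all__ = ["Dendrogram", "coniss", "cut"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Dendrogram:
    """Adjacency-constrained merge tree.

    ``merges`` is an ``(n-1, 2)`` integer array of cluster ids (leaves are
    ``0..n-1``, the cluster created by merge ``m`` has id ``n + m``).
    ``increments[m]`` is the dispersion increase of merge ``m`` and
    ``heights[m]`` the cumulative within-group dispersion after it.
    ``removed_boundaries[m]`` is the bin boundary erased by merge ``m``,
    so cutting into k clusters keeps exactly the boundaries removed by the
    last k-1 merges.
    """

    n_leaves: int
    merges: np.ndarray
    increments: np.ndarray
    heights: np.ndarray
    removed_boundaries: np.ndarray

    @property
    def total_dispersion(self) -> float:
        return float(self.heights[-1]) if self.heights.size else 0.0


def coniss(d: np.ndarray) -> Dendrogram:
    """Cluster a symmetric distance matrix under the adjacency constraint.

    At each step the adjacent pair with the smallest dispersion increment is
    merged (leftmost pair on ties) until a single cluster remains.
    """
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    if d.ndim != 2 or d.shape[1] != n:
        raise MatrixValidationError(f"distance matrix must be square, got {d.shape}")
    if n < 2:
        raise MatrixValidationError("need at least 2 items to cluster")
    if np.any(d < 0):
        raise MatrixValidationError("negative distances are not allowed")
    if not np.allclose(d, d.T, rtol=1e-12, atol=1e-12):
        raise MatrixValidationError("distance matrix must be symmetric")
    if np.any(np.diag(d) != 0):
        raise MatrixValidationError("distance matrix must have a zero diagonal")

    # merge-cost matrix between current clusters; for singletons the cost of
    # merging i and j is d_ij^2 / 2
    cost = d.astype(float) ** 2 / 2.0
    size = np.ones(n, dtype=float)
    cluster_id = np.arange(n)          # id of the active cluster anchored at each slot
    start = np.arange(n)               # leftmost leaf of the active cluster
    alive = np.ones(n, dtype=bool)

    merges = np.empty((n - 1, 2), dtype=int)
    increments = np.empty(n - 1, dtype=float)
    removed = np.empty(n - 1, dtype=int)

    active = list(range(n))  # slots of active clusters, left to right
    for m in range(n - 1):
        # cheapest adjacent pair; leftmost wins ties
        pair_costs = np.array(
            [cost[active[a], active[a + 1]] for a in range(len(active) - 1)]
        )
        a = int(np.argmin(pair_costs))
        if log.isEnabledFor(logging.DEBUG) and np.sum(pair_costs == pair_costs[a]) > 1:
            log.debug("merge %d: cost tie, leftmost adjacent pair chosen", m)
        i, j = active[a], active[a + 1]
        inc = cost[i, j]

        merges[m] = (cluster_id[i], cluster_id[j])
        increments[m] = inc
        removed[m] = start[j]

        # Lance-Williams (incremental sum of squares) update of merge costs
        others = [s for s in active if s != i and s != j]
        if others:
            o = np.array(others)
            ni, nj, nk = size[i], size[j], size[o]
            cost[i, o] = cost[o, i] = (
                (ni + nk) * cost[i, o] + (nj + nk) * cost[j, o] - nk * inc
            ) / (ni + nj + nk)
        size[i] += size[j]
        cluster_id[i] = n + m
        alive[j] = False
        active.pop(a + 1)

    heights = np.cumsum(increments)
    return Dendrogram(
        n_leaves=n,
        merges=merges,
        increments=increments,
        heights=heights,
        removed_boundaries=removed,
    )


def cut(dend: Dendrogram, k: int) -> Partition:
    """Undo the last ``k - 1`` merges, returning k contiguous segments."""
    n = dend.n_leaves
    if not 1 <= k <= n:
        raise ParameterError(f"k must be in [1, {n}], got {k}")
    boundaries = sorted(dend.removed_boundaries[n - k :].tolist())
    return Partition.from_boundaries(n, boundaries, level=k - 1)
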