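"""Level selection and joint PC-count / level optimization.

The number of significant dendrogram levels is chosen with the broken-stick
model; each (PC count, level) pair is scored with the Calinski-Harabasz
index; the PC count whose dendrogram has the highest mean CH over its
significant levels wins, and the level maximizing CH within that dendrogram
is the optimal segmentation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .conclust import Dendrogram, coniss, cut
from .dimreduce import (
    DEFAULT_N_PC_MAX,
    euclidean_distance_matrix,
    pca_reduce,
    pearson_transform,
)
from .errors import ParameterError, UndefinedMetricError
from .hic_io import BinMap, ContactMatrix
from .partition import Partition

__all__ = [
    "Hierarchy",
    "broken_stick_pieces",
    "broken_stick_max_level",
    "calinski_harabasz",
    "optimize",
    "map_partition",
    "write_hierarchy",
]


@dataclass
class Hierarchy:
    """Full result of the PC-count / level sweep.

    ``levels[L - 1]`` is the Partition at level L (L + 1 domains) of the
    winning dendrogram, in ORIGINAL bin coordinates.  ``ch_matrix[p - 1,
    L - 1]`` is the CH index for ``n_pc = p`` at level L (NaN where the
    level is not significant for that PC count).  ``has_hierarchy`` is
    False when no PC count yields any significant level.
    """

    has_hierarchy: bool
    n_pc_opt: int | None = None
    max_level: int = 0
    levels: list[Partition] = field(default_factory=list)
    optimal_level: int | None = None
    ch_matrix: np.ndarray | None = None
    dendrogram: Dendrogram | None = None
    n_bins: int = 0
    stable: bool | None = None
    stability_pvalue: float | None = None

    @property
    def n_tads_opt(self) -> int | None:
        """Optimal number of TADs: the optimal level plus 1."""
        return None if self.optimal_level is None else self.optimal_level + 1

    @property
    def optimal_partition(self) -> Partition | None:
        if self.optimal_level is None:
            return None
        return self.levels[self.optimal_level - 1]


def broken_stick_pieces(n: int) -> np.ndarray:
    """Expected sorted fractions of a unit stick broken into ``n`` pieces.

    ``b[g - 1] = (1/n) * sum_{i=g}^{n} 1/i``; the pieces sum to 1.
    """
    if n < 1:
        raise ParameterError(f"n must be >= 1, got {n}")
    inv = 1.0 / np.arange(1, n + 1)
    return np.cumsum(inv[::-1])[::-1] / n


def broken_stick_max_level(dend: Dendrogram, rule: str = "first_crossing") -> int:
    """Maximum significant number of dendrogram levels, ``max(N_D)``.

    For each split count ``g`` (2..n groups) the observed proportion of the
    total dispersion explained by the g-th split is compared with the
    broken-stick piece ``b_g``.  With ``rule='first_crossing'`` (default)
    the largest ``g`` with observed > expected for every split up to ``g``
    is taken; ``rule='any'`` takes the largest individually significant
    ``g``.  Level L corresponds to L + 1 groups, so the returned value is
    ``G - 1`` (0 = no significant hierarchy).
    """
    n = dend.n_leaves
    if n < 3:
        raise ParameterError(f"broken-stick selection needs >= 3 leaves, got {n}")
    total = dend.total_dispersion
    if total <= 0:
        return 0
    # split into g groups undoes merge n - g (0-based); its increment is the
    # dispersion explained by that split
    observed = dend.increments[::-1] / total          # g = 2 .. n
    expected = broken_stick_pieces(n)[1:]             # b_2 .. b_n
    significant = observed > expected
    if rule == "first_crossing":
        crossings = np.flatnonzero(~significant)
        n_groups = (crossings[0] + 1) if crossings.size else n
    elif rule == "any":
        hits = np.flatnonzero(significant)
        n_groups = (hits[-1] + 2) if hits.size else 1
    else:
        raise ParameterError(f"unknown rule {rule!r}")
    return int(n_groups) - 1


def calinski_harabasz(points: np.ndarray, labels) -> float:
    """Calinski-Harabasz index ``[B/(k-1)] / [W/(n-k)]``.

    B is the size-weighted squared deviation of cluster centroids from the
    grand centroid, W the within-cluster squared deviation.
    """
    x = np.atleast_2d(np.asarray(points, dtype=float))
    if x.shape[0] == 1:
        x = x.T
    lab = np.asarray(labels)
    n = x.shape[0]
    if lab.shape[0] != n:
        raise ParameterError("labels length must match number of points")
    uniq = np.unique(lab)
    k = uniq.size
    if k < 2 or k >= n:
        raise UndefinedMetricError(f"CH undefined for k={k} clusters of n={n} points")
    grand = x.mean(axis=0)
    b = 0.0
    w = 0.0
    for u in uniq:
        grp = x[lab == u]
        c = grp.mean(axis=0)
        b += grp.shape[0] * float(np.sum((c - grand) ** 2))
        w += float(np.sum((grp - c) ** 2))
    if w == 0.0:
        return np.inf
    return (b / (k - 1)) / (w / (n - k))


def map_partition(p: Partition, bm: BinMap) -> Partition:
    """Re-express a partition of the filtered bins in original coordinates.

    Masked bins between two domains attach to the preceding domain; leading
    masked bins attach to the first domain.
    """
    starts = [0] + [int(bm.kept_to_original[s]) for s, _ in p.domains[1:]]
    ends = starts[1:] + [bm.n_original]
    return Partition(
        domains=list(zip(starts, ends)), level=p.level, ch_index=p.ch_index
    )


def _max_significant_ch(points: np.ndarray, bstick_rule: str) -> float:
    """Best CH over the broken-stick-significant levels of one clustering."""
    dist = squareform(pdist(points))
    dend = coniss(dist)
    max_nd = broken_stick_max_level(dend, rule=bstick_rule)
    best = 0.0
    for level in range(1, max_nd + 1):
        labels = cut(dend, level + 1).labels()
        best = max(best, calinski_harabasz(points, labels))
    return best


def optimize(
    m: ContactMatrix,
    bin_map: BinMap | None = None,
    n_pc_max: int = DEFAULT_N_PC_MAX,
    min_tads: int = 2,
    bstick_rule: str = "first_crossing",
    ch_on: str = "scores",
    stability_permutations: int = 19,
    rng: int | np.random.Generator | None = 0,
) -> Hierarchy:
    """Sweep PC counts, score every significant level, return the Hierarchy.

    ``m`` must already be filtered (no bad bins); ``bin_map`` maps results
    back to original coordinates (identity if omitted).  ``min_tads``
    restricts the levels entering the mean-CH comparison and the arg-max to
    those with at least that many domains (benchmark mode uses 10).
    ``ch_on`` computes CH either on the PC scores (default) or on the rows
    of the Euclidean distance matrix (``'distances'``).

    A hierarchy that passes the broken-stick cut can still be an artifact
    of noise, so the winning level is additionally screened against
    ``stability_permutations`` bin-shuffled replicates of the winning
    scores (adjacency destroyed, geometry preserved): the result is
    flagged ``stable`` only when the observed optimal CH exceeds every
    permutation's best significant CH (one-sided empirical p-value in
    ``stability_pvalue``).  ``rng`` seeds only this screen; pass
    ``stability_permutations=0`` to skip it.
    """
    if min_tads < 2:
        raise ParameterError(f"min_tads must be >= 2, got {min_tads}")
    if ch_on not in ("scores", "distances"):
        raise ParameterError(f"ch_on must be 'scores' or 'distances', got {ch_on!r}")
    bm = bin_map if bin_map is not None else BinMap.identity(m.n_bins)

    pcc = pearson_transform(m)
    emb = pca_reduce(pcc, n_pc_max=n_pc_max)
    n_pcs = emb.n_components
    n = m.n_bins

    ch_matrix = np.full((n_pcs, n - 1), np.nan)
    dendrograms: list[Dendrogram] = []
    max_levels = np.zeros(n_pcs, dtype=int)

    for p_idx in range(n_pcs):
        n_pc = p_idx + 1
        dist = euclidean_distance_matrix(emb, n_pc)
        dend = coniss(dist)
        dendrograms.append(dend)
        max_nd = broken_stick_max_level(dend, rule=bstick_rule)
        max_levels[p_idx] = max_nd
        pts = emb.scores[:, :n_pc] if ch_on == "scores" else dist
        for level in range(1, max_nd + 1):
            labels = cut(dend, level + 1).labels()
            ch_matrix[p_idx, level - 1] = calinski_harabasz(pts, labels)

    # mean CH over each dendrogram's significant levels with >= min_tads domains
    mean_ch = np.full(n_pcs, np.nan)
    for p_idx in range(n_pcs):
        row = ch_matrix[p_idx, : max_levels[p_idx]]
        eligible = row[max(min_tads - 2, 0) :]
        eligible = eligible[np.isfinite(eligible)]
        if eligible.size:
            mean_ch[p_idx] = eligible.mean()

    if not np.any(np.isfinite(mean_ch)):
        return Hierarchy(has_hierarchy=False, ch_matrix=ch_matrix, n_bins=bm.n_original)

    winner = int(np.nanargmax(mean_ch))  # first max -> smallest n_pc on ties
    win_dend = dendrograms[winner]
    win_max = int(max_levels[winner])
    win_row = ch_matrix[winner, :win_max]
    considered = np.arange(1, win_max + 1)
    ok = considered + 1 >= min_tads
    best_pos = int(np.nanargmax(np.where(ok, win_row, -np.inf)))
    optimal_level = best_pos + 1

    levels = []
    for level in range(1, win_max + 1):
        part = cut(win_dend, level + 1)
        part.ch_index = float(win_row[level - 1])
        levels.append(map_partition(part, bm))

    stable = None
    stability_pvalue = None
    if stability_permutations > 0:
        gen = np.random.default_rng(rng)
        observed_ch = float(win_row[optimal_level - 1])
        win_pts = emb.scores[:, : winner + 1]
        exceed = 0
        for _ in range(stability_permutations):
            perm = gen.permutation(win_pts.shape[0])
            if _max_significant_ch(win_pts[perm], bstick_rule) >= observed_ch:
                exceed += 1
        stability_pvalue = (exceed + 1.0) / (stability_permutations + 1.0)
        stable = exceed == 0

    trimmed = ch_matrix[:, : max(int(max_levels.max()), 1)]
    return Hierarchy(
        has_hierarchy=True,
        n_pc_opt=winner + 1,
        max_level=win_max,
        levels=levels,
        optimal_level=optimal_level,
        ch_matrix=trimmed,
        dendrogram=win_dend,
        n_bins=bm.n_original,
        stable=stable,
        stability_pvalue=stability_pvalue,
    )


def write_hierarchy(
    h: Hierarchy,
    prefix: str,
    chrom: str = "chrN",
    start_bp: int = 0,
    resolution: int = 1,
) -> dict[str, str]:
    """Write level BEDs, a summary TSV and a JSON dump; returns file paths."""
    from . import bedio

    paths = {
        "domains": f"{prefix}_domains.bed",
        "summary": f"{prefix}_summary.tsv",
        "json": f"{prefix}_result.json",
    }
    bedio.write_partitions(
        paths["domains"], h.levels, chrom=chrom, start_bp=start_bp, resolution=resolution
    )
    with open(paths["summary"], "w") as fh:
        fh.write("level\tn_domains\tch_index\toptimal\n")
        for part in h.levels:
            fh.write(
                f"{part.level}\t{part.n_domains}\t{part.ch_index}\t"
                f"{int(part.level == h.optimal_level)}\n"
            )
    payload = {
        "has_hierarchy": h.has_hierarchy,
        "stable": h.stable,
        "stability_pvalue": h.stability_pvalue,
        "chrom": chrom,
        "start_bp": start_bp,
        "resolution": resolution,
        "n_bins": h.n_bins,
        "n_pc_opt": h.n_pc_opt,
        "max_level": h.max_level,
        "optimal_level": h.optimal_level,
        "n_tads_opt": h.n_tads_opt,
        "levels": [
            {
                "level": p.level,
                "ch_index": p.ch_index,
                "domains": [
                    [start_bp + s * resolution, start_bp + e * resolution]
                    for s, e in p.domains
                ],
            }
            for p in h.levels
        ],
    }
    with open(paths["json"], "w") as fh:
        json.dump(payload, fh, indent=2)
    return paths
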