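"""Partition-comparison metrics: Measure of Concordance and border overlap."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import MatrixValidationError, ParameterError, UndefinedMetricError
from .partition import Partition

__all__ = ["DomainSet", "moc", "overlap_score", "overlap_pvalue"]


@dataclass(frozen=True)
class DomainSet:
    """Ordered, contiguous genomic intervals (base pairs) covering a region."""

    domains: tuple
    chrom: str = "chrN"

    def __post_init__(self) -> None:
        doms = tuple((int(s), int(e)) for s, e in self.domains)
        object.__setattr__(self, "domains", doms)
        if not doms:
            raise MatrixValidationError("DomainSet needs at least one domain")
        for (s, e) in doms:
            if e <= s:
                raise MatrixValidationError(f"empty or inverted domain ({s},{e})")
        for (_, e0), (s1, _) in zip(doms, doms[1:]):
            if s1 != e0:
                raise MatrixValidationError(
                    f"domains must be contiguous; break at {e0}..{s1}"
                )

    @property
    def n(self) -> int:
        return len(self.domains)

    @property
    def start(self) -> int:
        return self.domains[0][0]

    @property
    def end(self) -> int:
        return self.domains[-1][1]

    @property
    def sizes(self) -> np.ndarray:
        return np.array([e - s for s, e in self.domains], dtype=float)

    @property
    def borders(self) -> np.ndarray:
        """Internal borders only; the region ends are excluded."""
        return np.array([s for s, _ in self.domains[1:]], dtype=int)

    @classmethod
    def from_partition(
        cls, p: Partition, start_bp: int = 0, resolution: int = 1, chrom: str = "chrN"
    ) -> "DomainSet":
        return cls(
            domains=tuple(
                (start_bp + s * resolution, start_bp + e * resolution)
                for s, e in p.domains
            ),
            chrom=chrom,
        )


def moc(p: DomainSet, q: DomainSet) -> float:
    """Measure of Concordance between two partitions of the same region.

    1 when both are a single domain; otherwise
    ``(1 / (sqrt(Np * Nq) - 1)) * (sum_ij F_ij^2 / (|P_i| |Q_j|) - 1)``
    with ``F_ij`` the overlap size in base pairs.  Ranges from 0
    (discordant) to 1 (identical).
    """
    if (p.start, p.end) != (q.start, q.end):
        raise MatrixValidationError(
            f"partitions cover different extents: [{p.start},{p.end}) vs "
            f"[{q.start},{q.end})"
        )
    if p.n == 1 and q.n == 1:
        return 1.0
    acc = 0.0
    for ps, pe in p.domains:
        for qs, qe in q.domains:
            f = min(pe, qe) - max(ps, qs)
            if f > 0:
                acc += f * f / ((pe - ps) * (qe - qs))
    return (acc - 1.0) / (np.sqrt(p.n * q.n) - 1.0)


def overlap_score(
    fine: DomainSet, coarse: DomainSet, tol_bins: int = 1, resolution: int = 1
) -> float:
    """Percentage of coarse borders with a fine border within ``tol_bins``.

    Tolerance is expressed in bins of the finer set's ``resolution``; only
    internal borders count.
    """
    fine_borders = fine.borders
    coarse_borders = coarse.borders
    if fine_borders.size == 0 or coarse_borders.size == 0:
        raise UndefinedMetricError("overlap score undefined without internal borders")
    tol_bp = tol_bins * resolution
    nearest = np.abs(coarse_borders[:, None] - fine_borders[None, :]).min(axis=1)
    return 100.0 * float(np.mean(nearest <= tol_bp))


def overlap_pvalue(
    fine: DomainSet,
    coarse: DomainSet,
    n_rand: int = 10_000,
    tol_bins: int = 1,
    resolution: int = 1,
    rng=None,
) -> float:
    """Permutation p-value for the border overlap score.

    Random fine-resolution partitions with the observed fine domain count
    are drawn over the same extent; p is the add-one-corrected fraction
    with overlap >= observed.
    """
    if n_rand < 1:
        raise ParameterError(f"n_rand must be >= 1, got {n_rand}")
    rng = np.random.default_rng(rng)
    observed = overlap_score(fine, coarse, tol_bins=tol_bins, resolution=resolution)
    n_bins = (fine.end - fine.start) // resolution
    if n_bins < fine.n:
        raise ParameterError("resolution too coarse for the fine domain count")
    count = 0
    positions = np.arange(1, n_bins)
    for _ in range(n_rand):
        cuts = np.sort(rng.choice(positions, size=fine.n - 1, replace=False))
        bps = fine.start + cuts * resolution
        edges = [fine.start, *bps.tolist(), fine.end]
        rand_set = DomainSet(domains=tuple(zip(edges[:-1], edges[1:])), chrom=fine.chrom)
        score = overlap_score(rand_set, coarse, tol_bins=tol_bins, resolution=resolution)
        if score >= observed:
            count += 1
    return (count + 1.0) / (n_rand + 1.0)
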