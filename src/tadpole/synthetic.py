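"""Synthetic nested block-structured contact matrices with known truth.

Expected counts follow a power-law distance decay multiplied by a block
enrichment factor for every nesting level at which two bins share a
domain; observed counts are Poisson draws, symmetrized by mirroring the
upper triangle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError
from .hic_io import ContactMatrix
from .partition import Partition
from .enrichment import PeakSet

__all__ = ["SyntheticSpec", "generate_matrix", "generate_peaks"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a nested block matrix.

    ``levels`` is a list of strictly nested boundary sets (each later set
    contains all earlier boundaries); ``block_contrast`` multiplies the
    expected counts once per nesting depth shared by a bin pair.
    """

    n_bins: int
    levels: tuple = ()
    block_contrast: float | tuple = 3.0
    distance_decay_exponent: float = 1.0
    base_intensity: float = 100.0
    bad_column_fraction: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        lv = tuple(tuple(sorted(int(b) for b in bs)) for bs in self.levels)
        object.__setattr__(self, "levels", lv)
        contrast = self.block_contrast
        if np.ndim(contrast) == 0:
            contrast = (float(contrast),) * len(lv)
        else:
            contrast = tuple(float(c) for c in contrast)
            if len(contrast) != len(lv):
                raise ParameterError(
                    "block_contrast sequence must have one entry per level"
                )
        object.__setattr__(self, "block_contrast", contrast)
        if any(c <= 0 for c in contrast):
            raise ParameterError("block_contrast entries must be positive")
        if self.n_bins < 4:
            raise ParameterError("n_bins must be >= 4")
        if self.base_intensity <= 0:
            raise ParameterError("base_intensity must be positive")
        if not 0.0 <= self.bad_column_fraction < 1.0:
            raise ParameterError("bad_column_fraction must be in [0, 1)")
        prev: set = set()
        for bs in lv:
            if any(not 0 < b < self.n_bins for b in bs):
                raise ParameterError(f"boundaries {bs} out of range (0, {self.n_bins})")
            if len(set(bs)) != len(bs):
                raise ParameterError(f"duplicate boundaries in {bs}")
            if not prev.issubset(set(bs)) or set(bs) == prev:
                raise ParameterError("level boundary sets must be strictly nested")
            prev = set(bs)


def expected_counts(spec: SyntheticSpec) -> np.ndarray:
    """Noise-free expected count matrix for ``spec``."""
    n = spec.n_bins
    idx = np.arange(n)
    dist = np.abs(idx[:, None] - idx[None, :])
    expected = spec.base_intensity * (1.0 + dist) ** (-spec.distance_decay_exponent)
    for bs, contrast in zip(spec.levels, spec.block_contrast):
        labels = Partition.from_boundaries(n, bs).labels()
        same = labels[:, None] == labels[None, :]
        expected = np.where(same, expected * contrast, expected)
    return expected


def generate_matrix(spec: SyntheticSpec) -> tuple[ContactMatrix, list[Partition]]:
    """Sample a matrix from ``spec``; returns it with the planted partitions.

    The truth list holds one Partition per nesting level, shallowest first.
    """
    rng = np.random.default_rng(spec.seed)
    expected = expected_counts(spec)
    upper = rng.poisson(expected).astype(float)
    values = np.triu(upper)
    values = values + np.triu(values, 1).T

    n = spec.n_bins
    n_bad = int(round(spec.bad_column_fraction * n))
    if n_bad:
        bad = rng.choice(n, size=n_bad, replace=False)
        values[bad, :] = 0.0
        values[:, bad] = 0.0

    cm = ContactMatrix(chrom="chrS", start_bp=0, resolution=1, values=values)
    truth = [Partition.from_boundaries(n, bs) for bs in spec.levels]
    return cm, truth


def generate_peaks(
    truth_boundaries_bp,
    region_end_bp: int,
    hit_rate: float = 1.0,
    background_rate: float = 0.0,
    peak_width: int = 2_000,
    slot: int = 5_000,
    rng=None,
    chrom: str = "chrS",
) -> PeakSet:
    """Peaks at planted boundaries plus uniform background.

    Each boundary gains a centered peak with probability ``hit_rate``; each
    ``slot``-sized window of the region gains a background peak with
    probability ``background_rate``.
    """
    if not 0.0 <= hit_rate <= 1.0 or not 0.0 <= background_rate <= 1.0:
        raise ParameterError("rates must be in [0, 1]")
    rng = np.random.default_rng(rng)
    half = peak_width // 2
    intervals = []
    for b in np.asarray(truth_boundaries_bp, dtype=int):
        if rng.random() < hit_rate:
            intervals.append((max(b - half, 0), b + half))
    for start in range(0, region_end_bp, slot):
        if rng.random() < background_rate:
            center = start + slot // 2
            intervals.append((max(center - half, 0), center + half))
    arr = np.array(intervals) if intervals else np.empty((0, 2), int)
    return PeakSet(intervals=arr, chrom=chrom)
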