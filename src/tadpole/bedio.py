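"""BED/bedGraph/TSV readers and writers shared by the CLI subcommands.

All coordinates are 0-based half-open, BED style.  Domain BED files carry
``chrom, start, end, level, domain_index, ch_index`` columns; a partition
at hierarchy level L occupies the rows with ``level == L``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .concordance import DomainSet
from .enrichment import PeakSet, SignalTrack
from .errors import MatrixFormatError
from .partition import Partition

__all__ = [
    "write_partitions",
    "read_partition_bed",
    "read_domainset",
    "read_peaks",
    "read_bedgraph",
]

_DOMAIN_COLS = ["chrom", "start", "end", "level", "domain", "ch_index"]


def write_partitions(
    path,
    partitions: list[Partition],
    chrom: str = "chrN",
    start_bp: int = 0,
    resolution: int = 1,
) -> None:
    rows = []
    for part in partitions:
        for d, (s, e) in enumerate(part.domains):
            rows.append(
                (
                    chrom,
                    start_bp + s * resolution,
                    start_bp + e * resolution,
                    part.level,
                    d,
                    "" if part.ch_index is None else part.ch_index,
                )
            )
    pd.DataFrame(rows, columns=_DOMAIN_COLS).to_csv(
        path, sep="\t", header=False, index=False
    )


def _read_bed_frame(path, n_cols_min: int = 3) -> pd.DataFrame:
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#")
    if df.shape[1] < n_cols_min:
        raise MatrixFormatError(f"{path}: expected >= {n_cols_min} BED columns")
    return df


def read_partition_bed(
    path, level: int | None = None, start_bp: int = 0, resolution: int = 1
):
    """Read one partition (bin coordinates) from a domain BED file.

    With ``level`` the rows of that hierarchy level are selected (column 4);
    otherwise the file must contain a single partition.
    """
    df = _read_bed_frame(path)
    if level is not None:
        if df.shape[1] < 4:
            raise MatrixFormatError(f"{path}: no level column to select level {level}")
        df = df[df[3] == level]
        if df.empty:
            raise MatrixFormatError(f"{path}: no rows at level {level}")
    df = df.sort_values(1)
    domains = [
        ((int(s) - start_bp) // resolution, (int(e) - start_bp) // resolution)
        for s, e in zip(df[1], df[2])
    ]
    return Partition(domains=domains)


def read_domainset(path, level: int | None = None) -> DomainSet:
    """Read one partition in genomic (bp) coordinates."""
    df = _read_bed_frame(path)
    if level is not None and df.shape[1] >= 4:
        df = df[df[3] == level]
    df = df.sort_values(1)
    return DomainSet(
        domains=tuple((int(s), int(e)) for s, e in zip(df[1], df[2])),
        chrom=str(df.iloc[0, 0]),
    )


def read_peaks(path, chrom: str | None = None) -> PeakSet:
    df = _read_bed_frame(path)
    if chrom is not None:
        df = df[df[0] == chrom]
    arr = df[[1, 2]].to_numpy(dtype=int) if len(df) else np.empty((0, 2), int)
    label = chrom or (str(df.iloc[0, 0]) if len(df) else "chrN")
    return PeakSet(intervals=arr, chrom=label)


def read_bedgraph(path, chrom: str | None = None) -> SignalTrack:
    """Read a uniformly binned bedGraph into a SignalTrack."""
    df = _read_bed_frame(path, n_cols_min=4)
    if chrom is not None:
        df = df[df[0] == chrom]
    if df.empty:
        raise MatrixFormatError(f"{path}: no rows{' for ' + chrom if chrom else ''}")
    df = df.sort_values(1)
    starts = df[1].to_numpy(int)
    ends = df[2].to_numpy(int)
    sizes = np.unique(ends - starts)
    if sizes.size != 1:
        raise MatrixFormatError(f"{path}: bins are not uniform (sizes {sizes})")
    bin_size = int(sizes[0])
    if np.any(np.diff(starts) != bin_size):
        raise MatrixFormatError(f"{path}: bins are not contiguous")
    return SignalTrack(
        values=df[3].to_numpy(float),
        bin_size=bin_size,
        start_bp=int(starts[0]),
        chrom=str(df.iloc[0, 0]),
    )
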