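"""Reading, validating and filtering dense intra-chromosomal contact matrices.

The on-disk format is a whitespace/tab-separated dense square matrix of
raw or normalized interaction counts, optionally with a header row and/or
a leading label column (auto-detected).  All bins are 0-based internally;
genomic intervals are emitted half-open ``[start, end)``.
"""

from __future__ import annotations

import io
import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import MatrixFormatError, MatrixValidationError, ParameterError

__all__ = [
    "ContactMatrix",
    "BinMap",
    "read_matrix",
    "detect_bad_columns",
    "split_at_centromere",
    "drop_masked",
]

#: Relative tolerance used to accept small asymmetries before symmetrizing.
DEFAULT_SYMMETRY_RTOL = 1e-6


@dataclass
class ContactMatrix:
    """Dense symmetric interaction matrix with bin metadata and bad-bin mask.

    Attributes
    ----------
    chrom : str
        Chromosome (or region) label.
    start_bp : int
        Genomic start of bin 0, 0-based base pairs.
    resolution : int
        Bin size in base pairs.
    values : numpy.ndarray
        ``(n_bins, n_bins)`` symmetric, non-negative float matrix.  Missing
        cells are stored as 0.
    bad_mask : numpy.ndarray
        Boolean vector, ``True`` marks an excluded (bad) bin.
    """

    chrom: str
    start_bp: int
    resolution: int
    values: np.ndarray
    bad_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise MatrixFormatError(
                f"contact matrix must be square, got shape {self.values.shape}"
            )
        if self.bad_mask is None:
            self.bad_mask = np.zeros(self.n_bins, dtype=bool)
        self.bad_mask = np.asarray(self.bad_mask, dtype=bool)
        if self.bad_mask.shape != (self.n_bins,):
            raise MatrixValidationError(
                f"bad_mask length {self.bad_mask.shape} != n_bins {self.n_bins}"
            )

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    def bin_to_bp(self, bin_index: int) -> int:
        """Genomic coordinate (bp) of the left edge of ``bin_index``."""
        return self.start_bp + bin_index * self.resolution


@dataclass(frozen=True)
class BinMap:
    """Mapping between filtered (bad bins removed) and original bin indices."""

    kept_to_original: np.ndarray
    n_original: int

    def __post_init__(self) -> None:
        k2o = np.asarray(self.kept_to_original, dtype=int)
        object.__setattr__(self, "kept_to_original", k2o)
        if k2o.size and np.any(np.diff(k2o) <= 0):
            raise MatrixValidationError("kept_to_original must be strictly increasing")

    @property
    def n_kept(self) -> int:
        return self.kept_to_original.size

    @property
    def original_to_kept(self) -> np.ndarray:
        """Inverse partial map; -1 for bins that were dropped."""
        inv = np.full(self.n_original, -1, dtype=int)
        inv[self.kept_to_original] = np.arange(self.n_kept)
        return inv

    @classmethod
    def identity(cls, n: int) -> "BinMap":
        return cls(kept_to_original=np.arange(n), n_original=n)


_NA_TOKENS = {"na", "nan", "n/a", "null", "none", ""}


def _is_number(token: str) -> bool:
    if token.lower() in _NA_TOKENS:
        return True
    try:
        float(token)
        return True
    except ValueError:
        return False


def read_matrix(
    path,
    chrom: str = "chrN",
    start_bp: int = 0,
    resolution: int = 1,
    symmetry_rtol: float = DEFAULT_SYMMETRY_RTOL,
) -> ContactMatrix:
    """Read a dense square matrix from a tab/whitespace separated text file.

    A header row and/or a leading label column are auto-detected and
    discarded.  Missing cells (``NA``-like tokens) become 0.  The matrix is
    validated for squareness, finite non-negative entries and symmetry
    (relative tolerance ``symmetry_rtol``), then symmetrized exactly as
    ``(M + M.T) / 2``.
    """
    if hasattr(path, "read"):
        raw_lines = path.read().splitlines()
    else:
        with open(path) as fh:
            raw_lines = fh.read().splitlines()
    rows = [line.split() for line in raw_lines if line.strip()]
    if not rows:
        raise MatrixFormatError(f"{path}: empty matrix file")

    widths = {len(r) for r in rows}
    has_header = not all(_is_number(tok) for tok in rows[0][1:])
    body = rows[1:] if has_header else rows
    if not body:
        raise MatrixFormatError(f"{path}: no data rows")
    has_index = not all(_is_number(r[0]) for r in body)
    if has_index:
        body = [r[1:] for r in body]
    if len({len(r) for r in body}) != 1:
        raise MatrixFormatError(f"{path}: rows have unequal field counts {sorted(widths)}")
    ncol = len(body[0])
    if ncol < 2 or len(body) < 2:
        raise MatrixFormatError(f"{path}: matrix must be at least 2x2")
    if ncol != len(body):
        raise MatrixFormatError(
            f"{path}: matrix is not square ({len(body)} rows x {ncol} columns)"
        )
    for i, r in enumerate(body):
        for j, tok in enumerate(r):
            if not _is_number(tok):
                raise MatrixFormatError(f"{path}: non-numeric cell {tok!r} at ({i},{j})")

    frame = pd.read_csv(
        io.StringIO("\n".join(" ".join(r) for r in body)),
        sep=r"\s+",
        header=None,
        na_values=list(_NA_TOKENS),
    )
    values = frame.to_numpy(dtype=float)
    values = np.nan_to_num(values, nan=0.0)

    if np.any(~np.isfinite(values)):
        raise MatrixValidationError(f"{path}: non-finite entries present")
    if np.any(values < 0):
        i, j = np.argwhere(values < 0)[0]
        raise MatrixValidationError(f"{path}: negative entry {values[i, j]} at ({i},{j})")

    asym = np.abs(values - values.T)
    scale = max(np.abs(values).max(), 1.0)
    if asym.max() > symmetry_rtol * scale:
        i, j = np.unravel_index(np.argmax(asym), asym.shape)
        raise MatrixValidationError(
            f"{path}: asymmetry beyond tolerance at ({min(i, j)},{max(i, j)}): "
            f"M[{i},{j}]={values[i, j]} vs M[{j},{i}]={values[j, i]}"
        )
    values = (values + values.T) / 2.0

    return ContactMatrix(chrom=chrom, start_bp=start_bp, resolution=resolution, values=values)


def detect_bad_columns(
    m: ContactMatrix,
    percentile: float = 1.0,
    include_diagonal_bad_in_percentile: bool = True,
) -> ContactMatrix:
    """Mark low-quality bins; values are untouched, only ``bad_mask`` is set.

    A bin is bad when (a) its diagonal entry is zero/missing, or (b) its
    column sum is strictly below the given percentile of all column sums.
    The percentile (linear interpolation) is taken over all columns by
    default; set ``include_diagonal_bad_in_percentile=False`` to compute it
    only over columns that pass the diagonal rule.
    """
    if not 0.0 <= percentile <= 100.0:
        raise ParameterError(f"percentile must be in [0, 100], got {percentile}")
    diag_bad = np.diag(m.values) == 0.0
    colsums = m.values.sum(axis=0)
    pool = colsums if include_diagonal_bad_in_percentile else colsums[~diag_bad]
    if pool.size == 0:
        mask = diag_bad
    else:
        threshold = np.percentile(pool, percentile)
        mask = diag_bad | (colsums < threshold)
    return replace(m, bad_mask=mask)


def _zero_runs(is_zero: np.ndarray):
    """Yield (start, length) of each maximal run of True values."""
    pos = 0
    for val, grp in itertools.groupby(is_zero):
        length = sum(1 for _ in grp)
        if val:
            yield pos, length
        pos += length


def split_at_centromere(m: ContactMatrix) -> tuple[ContactMatrix, ContactMatrix]:
    """Split at the longest contiguous run of all-zero columns (the centromere).

    Ties between equal-length runs break to the leftmost.  Each arm keeps a
    correct ``start_bp`` and the corresponding slice of ``bad_mask``.
    """
    zero_col = m.values.sum(axis=0) == 0.0
    runs = list(_zero_runs(zero_col))
    if not runs:
        raise MatrixValidationError(
            "no all-zero column found; process the whole matrix instead of splitting"
        )
    start, length = max(runs, key=lambda r: r[1])  # max() keeps first on ties
    end = start + length
    left = ContactMatrix(
        chrom=m.chrom,
        start_bp=m.start_bp,
        resolution=m.resolution,
        values=m.values[:start, :start].copy(),
        bad_mask=m.bad_mask[:start].copy(),
    )
    right = ContactMatrix(
        chrom=m.chrom,
        start_bp=m.start_bp + end * m.resolution,
        resolution=m.resolution,
        values=m.values[end:, end:].copy(),
        bad_mask=m.bad_mask[end:].copy(),
    )
    return left, right


def drop_masked(m: ContactMatrix) -> tuple[ContactMatrix, BinMap]:
    """Restrict the matrix to unmasked bins; returns the filtered matrix + BinMap."""
    kept = np.flatnonzero(~m.bad_mask)
    if kept.size < 4:
        raise MatrixValidationError(
            f"only {kept.size} bins left after filtering; hierarchy needs >= 4"
        )
    sub = m.values[np.ix_(kept, kept)].copy()
    filtered = ContactMatrix(
        chrom=m.chrom, start_bp=m.start_bp, resolution=m.resolution, values=sub
    )
    return filtered, BinMap(kept_to_original=kept, n_original=m.n_bins)
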