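"""Boundary and TAD-body enrichment metrics from ChIP-seq peaks and tracks.

Peak profiles (SPP/HMP) count peaks in 5-kb slots across +/-500 kb around
each boundary; fold change and occupancy summarize boundary enrichment;
the TAD-body state test classifies domains as active/repressed from the
log10 ratio of a repressive over an active signal track.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .concordance import DomainSet
from .errors import ParameterError, UndefinedMetricError

__all__ = [
    "PeakSet",
    "SignalTrack",
    "spp_profile",
    "spp_offsets",
    "spp_fold_change",
    "boundary_occupancy",
    "consensus_and_union",
    "benjamini_hochberg",
    "tad_state_test",
    "TadStateResult",
]


@dataclass(frozen=True)
class PeakSet:
    """Sorted, merged-on-demand genomic intervals with BED semantics."""

    intervals: np.ndarray
    chrom: str = "chrN"

    def __post_init__(self) -> None:
        arr = np.asarray(self.intervals, dtype=int).reshape(-1, 2)
        arr = arr[np.lexsort((arr[:, 1], arr[:, 0]))]
        if arr.size and np.any(arr[:, 1] <= arr[:, 0]):
            raise ParameterError("peak intervals must have end > start")
        object.__setattr__(self, "intervals", arr)

    def __len__(self) -> int:
        return self.intervals.shape[0]

    def merged(self) -> "PeakSet":
        """Union of the intervals (overlapping/adjacent runs coalesced)."""
        if len(self) == 0:
            return self
        out = []
        cur_s, cur_e = self.intervals[0]
        for s, e in self.intervals[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                out.append((cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append((cur_s, cur_e))
        return PeakSet(intervals=np.array(out), chrom=self.chrom)


@dataclass(frozen=True)
class SignalTrack:
    """Uniformly binned real-valued signal (e.g. fold change over control)."""

    values: np.ndarray
    bin_size: int
    start_bp: int = 0
    chrom: str = "chrN"

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.bin_size < 1:
            raise ParameterError("bin_size must be >= 1 bp")

    @property
    def end_bp(self) -> int:
        return self.start_bp + self.values.size * self.bin_size


def _coverage_steps(peaksets):
    """Breakpoint sweep: positions and per-set coverage deltas pooled."""
    events = []
    for ps in peaksets:
        for s, e in ps.intervals:
            events.append((s, 1))
            events.append((e, -1))
    return events


def consensus_and_union(peaksets) -> tuple[PeakSet, PeakSet]:
    """(consensus, union) of replicate peak sets.

    Union: intervals covered by at least one replicate, merged.  Consensus:
    positions covered by every replicate, merged.
    """
    peaksets = list(peaksets)
    if not peaksets:
        raise ParameterError("need at least one peak set")
    chrom = peaksets[0].chrom
    union = PeakSet(
        intervals=np.concatenate([ps.intervals for ps in peaksets])
        if any(len(ps) for ps in peaksets)
        else np.empty((0, 2), int),
        chrom=chrom,
    ).merged()

    # sweep the pooled breakpoints counting how many replicates cover a point
    need = len(peaksets)
    events = sorted(_coverage_steps(PeakSet(ps.merged().intervals, chrom) for ps in peaksets))
    depth = 0
    open_start = None
    pieces = []
    for pos, delta in events:
        new_depth = depth + delta
        if depth < need <= new_depth:
            open_start = pos
        elif new_depth < need <= depth and open_start is not None:
            if pos > open_start:
                pieces.append((open_start, pos))
            open_start = None
        depth = new_depth
    consensus = PeakSet(
        intervals=np.array(pieces) if pieces else np.empty((0, 2), int), chrom=chrom
    ).merged()
    return consensus, union


def spp_offsets(half_window: int = 500_000, step: int = 5_000) -> np.ndarray:
    """Left-edge offsets of the slots relative to the boundary.

    The grid spans ``[-half_window, +half_window)`` in ``2 * half_window /
    step`` slots; the slot with offset 0 (index ``half_window // step``)
    contains the boundary position.
    """
    n_side = half_window // step
    return np.arange(-n_side, n_side) * step


def spp_profile(
    boundaries,
    peaks: PeakSet,
    half_window: int = 500_000,
    step: int = 5_000,
) -> np.ndarray:
    """Structural-protein/histone-mark profile around boundaries.

    For each slot of the :func:`spp_offsets` grid, the value is the mean
    over boundaries of the number of peaks overlapping the slot.  Any
    overlap (>= 1 bp) counts.
    """
    boundaries = np.asarray(boundaries, dtype=int)
    if boundaries.size == 0:
        raise ParameterError("no boundaries supplied")
    n_slots = 2 * (half_window // step)
    counts = np.zeros(n_slots, dtype=float)
    for b in boundaries:
        grid0 = b - half_window  # left edge of slot 0
        for s, e in peaks.intervals:
            lo = int(np.floor((s - grid0) / step))
            hi = int(np.ceil((e - grid0) / step))  # slots [lo, hi) overlapped
            lo = max(lo, 0)
            hi = min(hi, n_slots)
            if hi > lo:
                counts[lo:hi] += 1
    return counts / boundaries.size


def spp_fold_change(
    profile: np.ndarray,
    step: int = 5_000,
    boundary_halfwidth_slots: int = 1,
    bg_offset: int = 400_000,
    bg_width: int = 100_000,
) -> float:
    """Boundary enrichment of an SPP: center over background ratio minus one.

    Center = mean of the boundary slot +/- ``boundary_halfwidth_slots``;
    background = mean of the slots inside the ``bg_width`` windows starting
    ``bg_offset`` away on each flank.  A flat profile gives 0.
    """
    profile = np.asarray(profile, dtype=float)
    n_slots = profile.size
    if n_slots % 2:
        raise ParameterError("profile length must be even (edge-aligned slot grid)")
    half_window = n_slots // 2 * step
    offsets = spp_offsets(half_window, step)
    centers = offsets + step / 2
    ci = n_slots // 2  # slot containing the boundary
    center_idx = np.zeros(n_slots, dtype=bool)
    center_idx[ci - boundary_halfwidth_slots : ci + boundary_halfwidth_slots + 1] = True
    bg_idx = (np.abs(centers) >= bg_offset) & (np.abs(centers) <= bg_offset + bg_width)
    background = profile[bg_idx].mean()
    if background == 0:
        raise UndefinedMetricError("background window has zero signal")
    return float(profile[center_idx].mean() / background - 1.0)


def boundary_occupancy(
    boundaries, peaks: PeakSet, tol_bins: int = 1, resolution: int = 1
) -> float:
    """Fraction of boundaries with >= 1 peak within +/- ``tol_bins`` matrix bins.

    The window of a boundary at position b spans the boundary bin plus
    ``tol_bins`` bins on each side: ``[b - tol*res, b + (tol+1)*res)``.
    """
    boundaries = np.asarray(boundaries, dtype=int)
    if boundaries.size == 0:
        raise ParameterError("no boundaries supplied")
    if len(peaks) == 0:
        return 0.0
    s = peaks.intervals[:, 0]
    e = peaks.intervals[:, 1]
    covered = 0
    for b in boundaries:
        lo = b - tol_bins * resolution
        hi = b + (tol_bins + 1) * resolution
        if np.any((s < hi) & (e > lo)):
            covered += 1
    return covered / boundaries.size


def benjamini_hochberg(pvalues) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, clipped to 1)."""
    p = np.asarray(pvalues, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


@dataclass(frozen=True)
class TadStateResult:
    """Outcome of the TAD-body active/repressed state test."""

    fraction_defined: float
    tad_fdr: np.ndarray
    log_ratio: np.ndarray
    pvalues: np.ndarray
    coarse_bin_size: int


def tad_state_test(
    tads: DomainSet,
    repressive: SignalTrack,
    active: SignalTrack,
    n_shuffle: int = 1_000,
    fdr: float = 0.1,
    rng=None,
    tad_fdr_rule: str = "min",
) -> TadStateResult:
    """Fraction of TADs with a significant repressive/active signal ratio.

    Both tracks are coarse-grained into bins spanning 10% of the mean TAD
    size and the log10 ratio repressive/active is computed per coarse bin
    (pseudocount: track-wide 1st percentile of positive values).  The null
    shuffles the paired fine-resolution track bins across the region and
    re-coarse-grains, so a coarse bin is significant when its coherent
    block signal is extreme relative to randomly re-pooled fine bins;
    two-sided empirical p-values are BH-adjusted within each TAD and the
    TAD's FDR is the minimum adjusted p (``tad_fdr_rule='min'``).  The
    returned fraction counts TADs with FDR < ``fdr``.
    """
    if n_shuffle < 1:
        raise ParameterError(f"n_shuffle must be >= 1, got {n_shuffle}")
    if tad_fdr_rule not in ("min", "median"):
        raise ParameterError(f"unknown tad_fdr_rule {tad_fdr_rule!r}")
    if repressive.bin_size != active.bin_size:
        raise ParameterError("tracks must share a bin size")
    rng = np.random.default_rng(rng)

    mean_size = (tads.end - tads.start) / tads.n
    fine = repressive.bin_size
    per_coarse = max(int(round(0.1 * mean_size / fine)), 1)
    coarse = per_coarse * fine

    def fine_values(track: SignalTrack) -> np.ndarray:
        """Track values on the region's fine grid (NaN outside the track)."""
        n_fine = -(-(tads.end - tads.start) // fine)
        vals = np.full(n_fine, np.nan)
        j0 = (tads.start - track.start_bp) // fine
        for i in range(n_fine):
            j = j0 + i
            if 0 <= j < track.values.size:
                vals[i] = track.values[j]
        return vals

    rep_fine = fine_values(repressive)
    act_fine = fine_values(active)

    def pseudocount(track: SignalTrack) -> float:
        pos = track.values[np.isfinite(track.values) & (track.values > 0)]
        return float(np.percentile(pos, 1)) if pos.size else 1.0

    eps_r, eps_a = pseudocount(repressive), pseudocount(active)

    def coarse_ratio(rep_f: np.ndarray, act_f: np.ndarray) -> np.ndarray:
        n_coarse = -(-rep_f.size // per_coarse)
        pad = n_coarse * per_coarse - rep_f.size
        if pad:
            rep_f = np.concatenate([rep_f, np.full(pad, np.nan)])
            act_f = np.concatenate([act_f, np.full(pad, np.nan)])
        with np.errstate(invalid="ignore"):
            rep_c = np.nanmean(rep_f.reshape(n_coarse, per_coarse), axis=1)
            act_c = np.nanmean(act_f.reshape(n_coarse, per_coarse), axis=1)
        out = np.log10((rep_c + eps_r) / (act_c + eps_a))
        return np.nan_to_num(out, nan=0.0)

    ratio = coarse_ratio(rep_fine, act_fine)

    exceed = np.zeros(ratio.size, dtype=int)
    for _ in range(n_shuffle):
        perm = rng.permutation(rep_fine.size)
        shuf = coarse_ratio(rep_fine[perm], act_fine[perm])
        exceed += np.abs(shuf) >= np.abs(ratio)
    pvals = (exceed + 1.0) / (n_shuffle + 1.0)

    centers = tads.start + (np.arange(ratio.size) + 0.5) * coarse
    tad_fdr = np.ones(tads.n)
    for t, (s, e) in enumerate(tads.domains):
        inside = (centers >= s) & (centers < e)
        if not inside.any():
            continue
        adj = benjamini_hochberg(pvals[inside])
        tad_fdr[t] = float(np.min(adj) if tad_fdr_rule == "min" else np.median(adj))
    fraction = float(np.mean(tad_fdr < fdr))
    return TadStateResult(
        fraction_defined=fraction,
        tad_fdr=tad_fdr,
        log_ratio=ratio,
        pvalues=pvals,
        coarse_bin_size=coarse,
    )
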