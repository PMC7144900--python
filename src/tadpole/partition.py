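"""Ordered contiguous segmentations of a binned region."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import MatrixValidationError

__all__ = ["Partition"]


@dataclass
class Partition:
    """A tiling of ``[0, n_bins)`` into contiguous half-open domains.

    ``level`` follows the dendrogram convention: level L = L + 1 domains.
    """

    domains: list[tuple[int, int]]
    level: int = None  # type: ignore[assignment]
    ch_index: float | None = None

    def __post_init__(self) -> None:
        self.domains = [(int(s), int(e)) for s, e in self.domains]
        if not self.domains:
            raise MatrixValidationError("partition must contain at least one domain")
        for (s, e) in self.domains:
            if e <= s:
                raise MatrixValidationError(f"empty or inverted domain ({s},{e})")
        for (_, e_prev), (s_next, _) in zip(self.domains, self.domains[1:]):
            if s_next != e_prev:
                raise MatrixValidationError(
                    f"domains must tile contiguously; gap/overlap at {e_prev}..{s_next}"
                )
        if self.level is None:
            self.level = len(self.domains) - 1
        elif self.level + 1 != len(self.domains):
            raise MatrixValidationError(
                f"level {self.level} implies {self.level + 1} domains, "
                f"got {len(self.domains)}"
            )

    @property
    def n_domains(self) -> int:
        return len(self.domains)

    @property
    def start(self) -> int:
        return self.domains[0][0]

    @property
    def end(self) -> int:
        return self.domains[-1][1]

    @property
    def n_bins(self) -> int:
        return self.end - self.start

    @property
    def boundaries(self) -> np.ndarray:
        """Internal boundaries: the start bin of every domain but the first."""
        return np.array([s for s, _ in self.domains[1:]], dtype=int)

    def labels(self) -> np.ndarray:
        """Per-bin domain index (0-based), length ``n_bins``."""
        lab = np.empty(self.n_bins, dtype=int)
        for i, (s, e) in enumerate(self.domains):
            lab[s - self.start : e - self.start] = i
        return lab

    @classmethod
    def from_boundaries(cls, n_bins: int, boundaries, **kw) -> "Partition":
        """Build from sorted internal boundary positions in ``(0, n_bins)``."""
        cuts = [0, *sorted(int(b) for b in boundaries), n_bins]
        return cls(domains=list(zip(cuts[:-1], cuts[1:])), **kw)

    @classmethod
    def from_labels(cls, labels, **kw) -> "Partition":
        lab = np.asarray(labels)
        change = np.flatnonzero(lab[1:] != lab[:-1]) + 1
        return cls.from_boundaries(lab.size, change, **kw)
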