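"""Binned tag-count tracks and RPM normalization.

A :class:`TagTrack` stores per-chromosome fixed-width bin counts and the
library size (total mapped tags). All signal statistics are reported as
reads per million mapped (RPM), the normalization used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import GenomeLayout
from .intervals import Interval


@dataclass
class TagTrack:
    counts: dict[str, np.ndarray]  # chrom -> int64 bin counts
    bin_width: int
    library_size: int

    @classmethod
    def from_counts(cls, counts: dict[str, np.ndarray], bin_width: int) -> "TagTrack":
        counts = {c: np.asarray(a, dtype=np.int64) for c, a in counts.items()}
        for chrom, arr in counts.items():
            if (arr < 0).any():
                raise ValueError(f"negative counts on {chrom}")
        lib = int(sum(int(a.sum()) for a in counts.values()))
        return cls(counts, bin_width, lib)

    @classmethod
    def zeros(cls, layout: GenomeLayout) -> "TagTrack":
        return cls.from_counts(
            {c: np.zeros(layout.n_bins(c), dtype=np.int64) for c in layout.chromosomes},
            layout.bin_width,
        )

    @property
    def total_bins(self) -> int:
        return sum(len(a) for a in self.counts.values())

    def mean_rate(self) -> float:
        """Genome-wide mean tags per bin."""
        if self.total_bins == 0:
            raise ValueError("empty track")
        return self.library_size / self.total_bins

    def bin_range(self, region: Interval) -> tuple[int, int]:
        """Half-open bin index range covering the region (partial bins included)."""
        first = region.start // self.bin_width
        last = -(-region.end // self.bin_width)
        n = len(self.counts[region.chromosome])
        return max(0, first), min(n, last)


def count_tags(track: TagTrack, region: Interval) -> int:
    """Tags in all bins fully or partially overlapped by the region.

    Partial bins are counted in full: tag positions are only known to
    bin resolution.
    """
    if track.total_bins == 0:
        raise ValueError("empty track")
    if region.chromosome not in track.counts:
        raise KeyError(f"unknown chromosome {region.chromosome!r}")
    lo, hi = track.bin_range(region)
    return int(track.counts[region.chromosome][lo:hi].sum())


def rpm(count: float, library_size: int) -> float:
    """Reads-per-million normalization: count x 1e6 / library size."""
    if library_size <= 0:
        raise ValueError("library size must be positive")
    return count * 1e6 / library_size
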