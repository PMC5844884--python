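"""Interval algebra and genomic-feature annotation.

All intervals are 0-based, half-open. A :class:`RegionSet` is a labeled,
merged (sorted, non-overlapping) collection of intervals — the substrate
of the enhancer logic: H3K4me1 peak sets per cell state, their three-way
overlap partition, and nearest-gene assignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genome import DISTAL_MIN, PROMOTER_WINDOW, GeneModel


@dataclass(frozen=True)
class Interval:
    chromosome: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chromosome}:{self.start}-{self.end}"
            )

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass
class RegionSet:
    """Sorted, non-overlapping intervals under a condition/mark label."""

    label: str
    intervals: list[Interval] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def total_bases(self) -> int:
        return sum(iv.span for iv in self.intervals)

    def is_merged(self) -> bool:
        prev: Interval | None = None
        for iv in self.intervals:
            if prev is not None and prev.chromosome == iv.chromosome:
                if iv.start < prev.end or (iv.start, iv.chromosome) < (
                    prev.start,
                    prev.chromosome,
                ):
                    return False
            prev = iv
        return True

    def by_chromosome(self) -> dict[str, np.ndarray]:
        """chrom -> (n, 2) array of [start, end), sorted."""
        out: dict[str, list[tuple[int, int]]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chromosome, []).append((iv.start, iv.end))
        return {
            c: np.asarray(sorted(pairs), dtype=np.int64) for c, pairs in out.items()
        }


def merge(intervals: Iterable[Interval], gap: int = 0, label: str = "") -> RegionSet:
    """Merge intervals into a minimal disjoint set.

    Intervals separated by ``gap`` bp or less are joined (gap=0 joins
    touching/overlapping intervals only).
    """
    if gap < 0:
        raise ValueError("gap must be non-negative")
    ivs = sorted(intervals, key=lambda iv: (iv.chromosome, iv.start, iv.end))
    merged: list[Interval] = []
    for iv in ivs:
        if (
            merged
            and merged[-1].chromosome == iv.chromosome
            and iv.start - merged[-1].end <= gap
        ):
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = Interval(last.chromosome, last.start, iv.end)
        else:
            merged.append(Interval(iv.chromosome, iv.start, iv.end))
    return RegionSet(label, merged)


def _overlaps_any(chrom_arrays: dict[str, np.ndarray], iv: Interval) -> bool:
    arr = chrom_arrays.get(iv.chromosome)
    if arr is None or len(arr) == 0:
        return False
    # first region with end > iv.start; overlap iff its start < iv.end
    idx = int(np.searchsorted(arr[:, 1], iv.start, side="right"))
    return idx < len(arr) and int(arr[idx, 0]) < iv.end


def venn_partition(
    set_wt: RegionSet, set_myc: RegionSet, set_m2: RegionSet
) -> list[tuple[Interval, tuple[int, int, int]]]:
    """Union components of three merged sets with 3-bit membership flags.

    Each connected component of the union of all three sets becomes one
    region; its membership bit for a condition is 1 iff the component
    overlaps that condition's set by at least 1 bp. The per-category
    base counts therefore sum to the union's base count.
    """
    for s in (set_wt, set_myc, set_m2):
        if not s.is_merged():
            raise ValueError(f"input set {s.label!r} is not merged")
    union = merge(
        [iv for s in (set_wt, set_myc, set_m2) for iv in s.intervals], gap=0
    )
    lookups = [s.by_chromosome() for s in (set_wt, set_myc, set_m2)]
    out = []
    for iv in union:
        bits = tuple(int(_overlaps_any(lk, iv)) for lk in lookups)
        out.append((iv, bits))
    return out


@dataclass(frozen=True)
class FeatureAnnotation:
    region: Interval
    feature_class: str  # promoter | exon | intron | intergenic
    nearest_gene: str
    signed_distance: int  # midpoint - TSS on the gene strand; negative = upstream


def _nearest_tss(
    midpoint: int,
    chrom: str,
    tss_by_chrom: dict[str, tuple[np.ndarray, list[GeneModel]]],
) -> GeneModel:
    if chrom not in tss_by_chrom:
        raise KeyError(f"no genes on chromosome {chrom!r}")
    tss_arr, gene_list = tss_by_chrom[chrom]
    dists = np.abs(tss_arr - midpoint)
    best = np.min(dists)
    # tie broken by lexicographic gene_id (gene_list pre-sorted by id within tss)
    candidates = [gene_list[i] for i in np.flatnonzero(dists == best)]
    return min(candidates, key=lambda g: g.gene_id)


def build_tss_index(
    genes: Sequence[GeneModel],
) -> dict[str, tuple[np.ndarray, list[GeneModel]]]:
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chromosome, []).append(g)
    out = {}
    for chrom, gs in by_chrom.items():
        gs = sorted(gs, key=lambda g: (g.tss, g.gene_id))
        out[chrom] = (np.array([g.tss for g in gs], dtype=np.int64), gs)
    return out


def annotate(
    region: Interval,
    genes: Sequence[GeneModel],
    promoter_window: tuple[int, int] = PROMOTER_WINDOW,
    tss_index: dict | None = None,
) -> FeatureAnnotation:
    """Classify a region by its midpoint and assign the nearest gene.

    Class priority when the midpoint falls into several feature types:
    promoter > exon > intron > intergenic. Nearest gene is by absolute
    midpoint-to-TSS distance, ties broken by lexicographic gene_id.
    """
    if not genes:
        raise ValueError("annotation requires at least one gene")
    index = tss_index if tss_index is not None else build_tss_index(genes)
    mid = region.midpoint
    nearest = _nearest_tss(mid, region.chromosome, index)
    if nearest.strand == "+":
        signed = mid - nearest.tss
    else:
        signed = nearest.tss - mid

    feature = "intergenic"
    in_exon = in_intron = in_promoter = False
    for g in genes:
        if g.chromosome != region.chromosome:
            continue
        ps, pe = g.promoter(promoter_window)
        if ps <= mid < pe:
            in_promoter = True
        if g.exons:
            span_s, span_e = g.span
            if span_s <= mid < span_e:
                if any(s <= mid < e for s, e in g.exons):
                    in_exon = True
                else:
                    in_intron = True
    if in_promoter:
        feature = "promoter"
    elif in_exon:
        feature = "exon"
    elif in_intron:
        feature = "intron"
    return FeatureAnnotation(region, feature, nearest.gene_id, int(signed))


def nearest_gene_distance(
    region: Interval, tss_index: dict
) -> tuple[str, int]:
    """Nearest gene_id and signed midpoint-to-TSS distance (fast path)."""
    nearest = _nearest_tss(region.midpoint, region.chromosome, tss_index)
    mid = region.midpoint
    signed = mid - nearest.tss if nearest.strand == "+" else nearest.tss - mid
    return nearest.gene_id, int(signed)


def is_distal(region: Interval, tss_index: dict, distal_min: int = DISTAL_MIN) -> bool:
    """True iff the region midpoint is > distal_min bp from every TSS."""
    entry = tss_index.get(region.chromosome)
    if entry is None:
        return True
    tss_arr, _ = entry
    return bool(np.min(np.abs(tss_arr - region.midpoint)) > distal_min)
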