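"""Genome layout and gene models.

Coordinates are 0-based, half-open (BED convention) throughout the
package; bedGraph tracks share the same convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Cell states profiled by the study design: parental immortalized mammary
#: epithelial cells (WT), the same cells overexpressing MYC, and
#: single-cell-derived secondary mammospheres (M2, the stem-like state).
CONDITIONS = ("WT", "MYC", "M2")

#: ChIP targets simulated and analyzed.
MARKS = ("MYC", "MIZ1", "H3K4me1", "H3K27ac", "H3K4me3")

#: Strand-oriented promoter window relative to the TSS, in bp:
#: [TSS - 1000, TSS + 100) on the gene strand.
PROMOTER_WINDOW = (-1000, 100)

#: A region is "distal" (enhancer-eligible) if its midpoint lies farther
#: than this from every TSS.
DISTAL_MIN = 2000


@dataclass(frozen=True)
class GenomeLayout:
    """Chromosome names and lengths plus the bin width of tag tracks.

    The last bin of a chromosome may be partial; bin_width need not
    divide the chromosome length.
    """

    lengths: dict[str, int]
    bin_width: int = 100

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if len(self.lengths) == 0:
            raise ValueError("layout needs at least one chromosome")
        for name, length in self.lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length")

    @property
    def chromosomes(self) -> tuple[str, ...]:
        return tuple(self.lengths)

    def n_bins(self, chrom: str) -> int:
        return -(-self.lengths[chrom] // self.bin_width)

    @property
    def total_bins(self) -> int:
        return sum(self.n_bins(c) for c in self.lengths)


@dataclass(frozen=True)
class GeneModel:
    """A gene with its TSS and exon structure.

    Exons are sorted, non-overlapping (start, end) pairs in genomic
    coordinates. The TSS equals the 5' exon boundary on the gene strand:
    the first exon start for '+' genes, the last exon end for '-' genes.
    """

    gene_id: str
    chromosome: str
    strand: str
    tss: int
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        prev_end = -1
        for s, e in self.exons:
            if not (0 <= s < e):
                raise ValueError(f"invalid exon ({s}, {e}) in {self.gene_id}")
            if s < prev_end:
                raise ValueError(f"exons overlap or unsorted in {self.gene_id}")
            prev_end = e
        if self.exons:
            expected = self.exons[0][0] if self.strand == "+" else self.exons[-1][1]
            if self.tss != expected:
                raise ValueError(
                    f"TSS {self.tss} is not the 5' exon boundary of {self.gene_id}"
                )

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def promoter(self, window: tuple[int, int] = PROMOTER_WINDOW) -> tuple[int, int]:
        """Strand-oriented promoter interval [TSS+up, TSS+down) in genomic coords."""
        up, down = window
        if self.strand == "+":
            return self.tss + up, self.tss + down
        return self.tss - down + 1, self.tss - up + 1


def genes_to_frame(genes: list[GeneModel]) -> pd.DataFrame:
    """Tabulate gene models (exons serialized as 'a-b;c-d')."""
    return pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "chromosome": [g.chromosome for g in genes],
            "strand": [g.strand for g in genes],
            "tss": [g.tss for g in genes],
            "exons": [";".join(f"{s}-{e}" for s, e in g.exons) for g in genes],
        }
    )


def genes_from_frame(df: pd.DataFrame) -> list[GeneModel]:
    genes = []
    for row in df.itertuples(index=False):
        exons = tuple(
            tuple(int(x) for x in part.split("-")) for part in row.exons.split(";")
        )
        genes.append(
            GeneModel(row.gene_id, row.chromosome, row.strand, int(row.tss), exons)
        )
    return genes


def tss_table(genes: list[GeneModel]) -> pd.DataFrame:
    """Per-gene TSS table sorted by (chromosome, tss, gene_id)."""
    df = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "chromosome": [g.chromosome for g in genes],
            "strand": [g.strand for g in genes],
            "tss": [g.tss for g in genes],
        }
    )
    return df.sort_values(["chromosome", "tss", "gene_id"], ignore_index=True)
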