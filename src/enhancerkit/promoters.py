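"""MYC-bound promoters: expression classes and MYC/MIZ1 occupancy ratio.

MYC binds two transcriptionally opposite promoter subsets: genes induced
on MYC overexpression and genes repressed. The repressed subset is
characterized by a low MYC/MIZ1 promoter occupancy ratio (MIZ1-dependent
direct repression), the induced subset by a high ratio.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .genome import PROMOTER_WINDOW, GeneModel
from .intervals import Interval, RegionSet, _overlaps_any
from .tracks import TagTrack, count_tags, rpm

logger = logging.getLogger(__name__)


def promoter_interval(gene: GeneModel, window: tuple[int, int] = PROMOTER_WINDOW) -> Interval:
    s, e = gene.promoter(window)
    return Interval(gene.chromosome, max(0, s), e, name=gene.gene_id)


def myc_bound_promoters(
    peak_sets: dict[str, RegionSet],
    genes: list[GeneModel],
    promoter_window: tuple[int, int] = PROMOTER_WINDOW,
) -> dict[str, set[str]]:
    """Genes whose promoter window overlaps >= 1 MYC peak, per condition."""
    out: dict[str, set[str]] = {}
    for cond, peaks in peak_sets.items():
        lookup = peaks.by_chromosome()
        bound = set()
        for g in genes:
            if _overlaps_any(lookup, promoter_interval(g, promoter_window)):
                bound.add(g.gene_id)
        out[cond] = bound
    return out


def classify_targets(
    bound_genes: set[str],
    fc_calls_myc_vs_wt: pd.DataFrame,
) -> pd.DataFrame:
    """Expression class of MYC-bound genes from MYC-vs-WT fold-change calls.

    up/down = bound and called up/down; otherwise unchanged. Bound genes
    absent from the (filtered) expression matrix are excluded with a log
    entry.
    """
    rows = []
    for gene in sorted(bound_genes):
        if gene not in fc_calls_myc_vs_wt.index:
            logger.info("gene %s not in expression matrix; unclassifiable", gene)
            continue
        rows.append(
            {
                "gene_id": gene,
                "fold_change": float(fc_calls_myc_vs_wt.loc[gene, "fold_change"]),
                "expression_class": fc_calls_myc_vs_wt.loc[gene, "call"],
            }
        )
    return pd.DataFrame(rows, columns=["gene_id", "fold_change", "expression_class"])


def myc_miz1_ratio(
    records: pd.DataFrame,
    genes: list[GeneModel],
    myc_track: TagTrack,
    miz1_track: TagTrack,
    promoter_window: tuple[int, int] = PROMOTER_WINDOW,
) -> pd.DataFrame:
    """MYC/MIZ1 RPM ratio over each gene's promoter window.

    ratio = (MYC RPM + eps_myc) / (MIZ1 RPM + eps_miz1) where eps is the
    RPM equivalent of a single tag in the respective library, so a
    promoter with zero counts in both tracks has ratio 1.
    """
    if myc_track.library_size <= 0 or miz1_track.library_size <= 0:
        raise ValueError("zero library size")
    gene_map = {g.gene_id: g for g in genes}
    eps_myc = rpm(1, myc_track.library_size)
    eps_miz1 = rpm(1, miz1_track.library_size)
    myc_rpms, miz1_rpms, ratios = [], [], []
    for gene_id in records["gene_id"]:
        g = gene_map[gene_id]
        win = promoter_interval(g, promoter_window)
        m = rpm(count_tags(myc_track, win), myc_track.library_size)
        z = rpm(count_tags(miz1_track, win), miz1_track.library_size)
        myc_rpms.append(m)
        miz1_rpms.append(z)
        ratios.append((m + eps_myc) / (z + eps_miz1))
    out = records.copy()
    out["myc_rpm"] = myc_rpms
    out["miz1_rpm"] = miz1_rpms
    out["myc_miz1_ratio"] = ratios
    return out


def compare_ratio_distributions(
    up_ratios: pd.Series | np.ndarray, down_ratios: pd.Series | np.ndarray
) -> dict:
    """Two-sided Wilcoxon rank-sum on log ratios of the two classes."""
    up = np.asarray(up_ratios, dtype=float)
    down = np.asarray(down_ratios, dtype=float)
    if len(up) == 0 or len(down) == 0:
        raise ValueError("both classes must be non-empty")
    res = stats.mannwhitneyu(np.log(up), np.log(down), alternative="two-sided")
    return {
        "median_up": float(np.median(up)),
        "median_down": float(np.median(down)),
        "statistic": float(res.statistic),
        "p_value": float(res.pvalue),
    }
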