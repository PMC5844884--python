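"""Enhancer-state classification across three cell states.

Putative enhancers are distal H3K4me1-marked regions taken from the
three-way overlap partition of the per-condition H3K4me1 domain sets
(WT, MYC-overexpressing, M2 mammospheres). H3K27ac overlays an activity
bit per condition — activity requires the region to be H3K4me1-primed in
that same condition — and the bit patterns resolve to state labels:

``wt_active_repressed``
    active (K27ac) in WT only — enhancers decommissioned on the way to
    the stem-like state.
``unchanged_active``
    primed and active in all three states.
``m2_de_novo``
    no H3K4me1 and no H3K27ac in either parental state (WT, MYC); both
    marks gained in M2.
``other_modulated``
    any remaining pattern with at least one active bit.
``inactive``
    primed somewhere but never active (K27ac 000).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genome import DISTAL_MIN, GeneModel
from .intervals import (
    Interval,
    RegionSet,
    build_tss_index,
    is_distal,
    nearest_gene_distance,
    venn_partition,
)

STATE_LABELS = (
    "wt_active_repressed",
    "unchanged_active",
    "m2_de_novo",
    "other_modulated",
    "inactive",
)

#: Minimum span (bp) for a putative enhancer region. Isolated single
#: significant windows are overwhelmingly sampling noise at the domain
#: caller's FDR; genuine primed enhancers are broad.
MIN_ENHANCER_SPAN = 1000


def classify_pattern(
    k4me1: tuple[int, int, int], k27ac: tuple[int, int, int]
) -> str:
    """State label from the (WT, MYC, M2) bit patterns.

    ``k27ac`` must already be gated on priming (bit can only be set where
    the H3K4me1 bit is set); classification is total over all patterns.
    """
    if k27ac == (0, 0, 0):
        return "inactive"
    if k4me1 == (0, 0, 1) and k27ac == (0, 0, 1):
        return "m2_de_novo"
    if k27ac == (1, 0, 0):
        return "wt_active_repressed"
    if k4me1 == (1, 1, 1) and k27ac == (1, 1, 1):
        return "unchanged_active"
    return "other_modulated"


def putative_enhancers(
    k4me1_domains: dict[str, RegionSet],
    genes: list[GeneModel],
    distal_min: int = DISTAL_MIN,
    min_span: int = MIN_ENHANCER_SPAN,
) -> pd.DataFrame:
    """Distal H3K4me1 union regions with per-condition membership bits.

    ``k4me1_domains`` maps each condition (WT, MYC, M2) to its merged
    H3K4me1 domain set. Union components narrower than ``min_span`` or
    with a midpoint within ``distal_min`` of any TSS are dropped.
    """
    parts = venn_partition(
        k4me1_domains["WT"], k4me1_domains["MYC"], k4me1_domains["M2"]
    )
    tss_index = build_tss_index(genes)
    rows = []
    for iv, bits in parts:
        if iv.span < min_span:
            continue
        if not is_distal(iv, tss_index, distal_min):
            continue
        rows.append(
            {
                "chromosome": iv.chromosome,
                "start": iv.start,
                "end": iv.end,
                "k4me1_wt": bits[0],
                "k4me1_myc": bits[1],
                "k4me1_m2": bits[2],
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["chromosome", "start", "end", "k4me1_wt", "k4me1_myc", "k4me1_m2"],
    )
    return df


def classify_states(
    records: pd.DataFrame, k27ac_domains: dict[str, RegionSet]
) -> pd.DataFrame:
    """Fill H3K27ac activity bits and state labels.

    A record is active in a condition iff it overlaps that condition's
    H3K27ac domain set by >= 1 bp AND carries the H3K4me1 bit there
    (activity requires priming).
    """
    out = records.copy()
    lookups = {c: k27ac_domains[c].by_chromosome() for c in ("WT", "MYC", "M2")}
    from .intervals import _overlaps_any

    for cond, col in (("WT", "wt"), ("MYC", "myc"), ("M2", "m2")):
        bits = []
        for row in out.itertuples(index=False):
            iv = Interval(row.chromosome, int(row.start), int(row.end))
            primed = getattr(row, f"k4me1_{col}")
            bits.append(int(bool(primed) and _overlaps_any(lookups[cond], iv)))
        out[f"k27ac_{col}"] = bits
    out["state"] = [
        classify_pattern(
            (r.k4me1_wt, r.k4me1_myc, r.k4me1_m2),
            (r.k27ac_wt, r.k27ac_myc, r.k27ac_m2),
        )
        for r in out.itertuples(index=False)
    ]
    return out


def assign_target_genes(
    records: pd.DataFrame, genes: list[GeneModel]
) -> pd.DataFrame:
    """Nearest-TSS target gene for every record (proximity criterion)."""
    if not genes:
        raise ValueError("annotation is empty")
    tss_index = build_tss_index(genes)
    names, dists = [], []
    for row in records.itertuples(index=False):
        iv = Interval(row.chromosome, int(row.start), int(row.end))
        gene, d = nearest_gene_distance(iv, tss_index)
        names.append(gene)
        dists.append(d)
    out = records.copy()
    out["nearest_gene"] = names
    out["distance"] = dists
    return out


def partition_by_myc(
    de_novo: pd.DataFrame, myc_differential: pd.DataFrame
) -> pd.DataFrame:
    """Split de novo enhancers by differential MYC binding gain in M2.

    ``myc_differential`` must contain every de novo region (keyed by
    chromosome/start/end); a record gains MYC iff its region is flagged
    differential with direction "up" in the M2-vs-MYC comparison.
    """
    key = ["chromosome", "start", "end"]
    diff = myc_differential.set_index(key)
    flags = []
    for row in de_novo.itertuples(index=False):
        k = (row.chromosome, row.start, row.end)
        if k not in diff.index:
            raise KeyError(f"region {k} missing from differential results")
        hit = diff.loc[k]
        flags.append(int(bool(hit["differential"]) and hit["direction"] == "up"))
    out = de_novo.copy()
    out["myc_gained_m2"] = flags
    return out


def summarize(
    records: pd.DataFrame, expression_fc: pd.Series | None = None
) -> dict:
    """State-level summary: counts, mean active span, median expression FC.

    ``expression_fc`` maps gene -> linear fold change (M2 vs MYC); the
    median FC of MYC-gained de novo enhancers is reported alongside the
    complement. Empty state classes appear with count 0 and no statistics.
    """
    summary: dict = {"states": {}}
    for state in STATE_LABELS:
        sub = records[records["state"] == state] if len(records) else records
        entry: dict = {"count": int(len(sub))}
        if len(sub):
            active = sub[
                (sub.get("k27ac_wt", 0) + sub.get("k27ac_myc", 0) + sub.get("k27ac_m2", 0))
                > 0
            ]
            spans = (sub["end"] - sub["start"]).to_numpy()
            entry["mean_span_bp"] = float(spans.mean())
            if len(active):
                entry["mean_active_span_bp"] = float(
                    (active["end"] - active["start"]).mean()
                )
            if expression_fc is not None and "nearest_gene" in sub:
                fcs = expression_fc.reindex(sub["nearest_gene"]).dropna()
                if len(fcs):
                    entry["median_expression_fc"] = float(fcs.median())
        summary["states"][state] = entry
    if "myc_gained_m2" in records.columns and expression_fc is not None:
        dn = records[records["state"] == "m2_de_novo"]
        for flag, name in ((1, "myc_gained"), (0, "not_gained")):
            sub = dn[dn["myc_gained_m2"] == flag]
            fcs = expression_fc.reindex(sub["nearest_gene"]).dropna()
            summary[f"median_fc_{name}"] = (
                float(fcs.median()) if len(fcs) else None
            )
    return summary
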