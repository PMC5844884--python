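"""Pipeline stages over on-disk artifacts.

Each stage reads the artifacts of its upstream stages from the output
directory, computes, and writes versioned plain-text outputs. A missing
upstream artifact raises :class:`DependencyError` naming the stage to
run first. The ``report`` stage aggregates the study-level numbers into
one JSON document.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import enhancers as enh
from . import expression as expr
from . import io
from . import motifs as mot
from . import promoters as prom
from . import survival as surv
from .config import PipelineConfig
from .enrichment import call_broad_domains, call_sharp_peaks, differential_regions
from .genome import CONDITIONS, MARKS, GenomeLayout, genes_from_frame, genes_to_frame
from .intervals import Interval
from .synth import PlantedTruth, simulate_sequences, simulate_study

logger = logging.getLogger(__name__)

SHARP_MARKS = ("MYC", "MIZ1")
BROAD_MARKS = ("H3K4me1", "H3K27ac", "H3K4me3")


class DependencyError(RuntimeError):
    """An upstream artifact is missing."""


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise DependencyError(
            f"missing upstream artifact {path.name!r}; run the {producer!r} stage first"
        )
    return path


def _log(outdir: Path, message: str) -> None:
    # no timestamps: the artifact set must be byte-identical across
    # repeated runs with the same seed
    with open(outdir / "pipeline.log", "a", newline="\n") as fh:
        fh.write(message + "\n")
    logger.info(message)


def _load_layout(outdir: Path) -> GenomeLayout:
    d = io.read_json(_require(outdir / "layout.json", "simulate"))
    return GenomeLayout({k: int(v) for k, v in d["lengths"].items()}, int(d["bin_width"]))


def _load_genes(outdir: Path):
    return genes_from_frame(io.read_tsv(_require(outdir / "annotation.tsv", "simulate")))


def _load_truth(outdir: Path) -> PlantedTruth:
    return PlantedTruth.from_dict(io.read_json(_require(outdir / "truth.json", "simulate")))


def _load_track(outdir: Path, layout: GenomeLayout, mark: str, cond: str):
    path = _require(outdir / "tracks" / f"{mark}_{cond}.bedgraph", "simulate")
    return io.read_bedgraph(path, layout)


# ---------------------------------------------------------------------------


def stage_simulate(cfg: PipelineConfig, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    study = simulate_study(cfg.study, seed=cfg.seed)
    io.write_json(
        outdir / "layout.json",
        {"lengths": study.layout.lengths, "bin_width": study.layout.bin_width},
    )
    io.write_tsv(outdir / "annotation.tsv", genes_to_frame(study.genes))
    io.write_json(outdir / "truth.json", study.truth.to_dict())

    (outdir / "tracks").mkdir(exist_ok=True)
    (outdir / "true_regions").mkdir(exist_ok=True)
    for (mark, cond), track in study.chip.tracks.items():
        io.write_bedgraph(
            outdir / "tracks" / f"{mark}_{cond}.bedgraph", track, study.layout
        )
    for (mark, cond), regions in study.chip.true_regions.items():
        io.write_bed(outdir / "true_regions" / f"{mark}_{cond}.bed", regions)

    io.write_tsv(outdir / "expression.tsv", study.expression.intensities, index=True)
    io.write_tsv(outdir / "detection_p.tsv", study.expression.detection_p, index=True)
    io.write_tsv(
        outdir / "samples.tsv",
        study.expression.conditions.rename_axis("sample").reset_index(),
    )
    io.write_tsv(
        outdir / "cohort_expression.tsv", study.cohort.cohort.expression, index=True
    )
    meta = study.cohort.cohort.meta.copy()
    meta["true_group"] = study.cohort.true_group
    io.write_tsv(outdir / "cohort_meta.tsv", meta.rename_axis("sample").reset_index())
    io.write_gmt(outdir / "genesets.gmt", study.gene_sets)

    sequences = simulate_sequences(study.layout, study.truth, seed=cfg.seed)
    io.write_fasta(outdir / "sequences.fa", sequences)
    io.write_json(outdir / "resolved_config.json", cfg.to_dict())
    _log(outdir, f"simulate: seed={cfg.seed} genes={len(study.genes)}")


def stage_chip(cfg: PipelineConfig, outdir: Path) -> None:
    layout = _load_layout(outdir)
    (outdir / "peaks").mkdir(exist_ok=True)
    (outdir / "domains").mkdir(exist_ok=True)
    for mark in SHARP_MARKS:
        for cond in CONDITIONS:
            track = _load_track(outdir, layout, mark, cond)
            peaks = call_sharp_peaks(track, p_threshold=cfg.sharp_p, label=f"{mark}_{cond}")
            io.write_bed(outdir / "peaks" / f"{mark}_{cond}.bed", peaks)
    for mark in BROAD_MARKS:
        for cond in CONDITIONS:
            track = _load_track(outdir, layout, mark, cond)
            domains = call_broad_domains(
                track,
                window=cfg.broad_window,
                gap=cfg.broad_gap,
                fdr=cfg.broad_fdr,
                label=f"{mark}_{cond}",
            )
            io.write_bed(outdir / "domains" / f"{mark}_{cond}.bed", domains)
    _log(outdir, "chip: peaks and domains called")


def stage_expression(cfg: PipelineConfig, outdir: Path) -> None:
    intens = io.read_tsv(_require(outdir / "expression.tsv", "simulate"), index_col=0)
    det = io.read_tsv(_require(outdir / "detection_p.tsv", "simulate"), index_col=0)
    samples = io.read_tsv(_require(outdir / "samples.tsv", "simulate"))
    conditions = samples.set_index("sample")["condition"]

    norm = expr.quantile_normalize(intens)
    filtered = expr.detection_filter(norm, det, alpha=cfg.detection_alpha)
    io.write_tsv(outdir / "expression_processed.tsv", filtered, index=True)

    for a, b, name in (("WT", "MYC", "fc_MYC_vs_WT"), ("MYC", "M2", "fc_M2_vs_MYC")):
        calls = expr.fold_change_calls(
            filtered, a, b, conditions, floor=cfg.expr_floor, threshold=cfg.expr_fold
        )
        io.write_tsv(outdir / f"{name}.tsv", calls.rename_axis("gene_id").reset_index())

    gene_sets = io.read_gmt(_require(outdir / "genesets.gmt", "simulate"))
    fc = io.read_tsv(outdir / "fc_MYC_vs_WT.tsv", index_col=0)
    ranked = np.log2(fc["fold_change"]).sort_values(ascending=False)
    gsea_out = {}
    for name, genes in gene_sets.items():
        members = [g for g in genes if g in ranked.index]
        if not members or len(members) == len(ranked):
            continue
        res = expr.gsea_preranked(
            ranked,
            members,
            set_name=name,
            weight=cfg.gsea_weight,
            n_perm=cfg.gsea_n_perm,
            seed=cfg.seed,
        )
        gsea_out[name] = {
            "es": res.es,
            "nes": res.nes,
            "p_value": res.p_value,
            "n_leading_edge": len(res.leading_edge),
        }
    io.write_json(outdir / "gsea.json", gsea_out)
    _log(outdir, "expression: normalized, filtered, fold changes, GSEA")


def stage_enhancers(cfg: PipelineConfig, outdir: Path) -> None:
    layout = _load_layout(outdir)
    genes = _load_genes(outdir)
    k4 = {
        c: io.read_bed(
            _require(outdir / "domains" / f"H3K4me1_{c}.bed", "chip"), f"H3K4me1_{c}"
        )
        for c in CONDITIONS
    }
    k27 = {
        c: io.read_bed(
            _require(outdir / "domains" / f"H3K27ac_{c}.bed", "chip"), f"H3K27ac_{c}"
        )
        for c in CONDITIONS
    }
    records = enh.putative_enhancers(
        k4, genes, distal_min=cfg.distal_min, min_span=cfg.min_enhancer_span
    )
    records = enh.classify_states(records, k27)
    records = enh.assign_target_genes(records, genes)

    de_novo = records[records["state"] == "m2_de_novo"]
    regions = [
        Interval(r.chromosome, int(r.start), int(r.end))
        for r in de_novo.itertuples(index=False)
    ]
    myc_m2 = _load_track(outdir, layout, "MYC", "M2")
    myc_myc = _load_track(outdir, layout, "MYC", "MYC")
    diff = differential_regions(
        regions, myc_m2, myc_myc, min_fold=cfg.diff_fold, p_max=cfg.diff_p
    )
    io.write_tsv(outdir / "myc_differential_denovo.tsv", diff)
    if len(de_novo):
        de_novo = enh.partition_by_myc(de_novo, diff)
        records = records.merge(
            de_novo[["chromosome", "start", "end", "myc_gained_m2"]],
            on=["chromosome", "start", "end"],
            how="left",
        )
        records["myc_gained_m2"] = records["myc_gained_m2"].fillna(0).astype(int)
    else:
        records["myc_gained_m2"] = pd.Series(dtype=int)

    fc_path = _require(outdir / "fc_M2_vs_MYC.tsv", "expression")
    fc = io.read_tsv(fc_path, index_col=0)["fold_change"]
    records["expression_fc_m2_vs_myc"] = fc.reindex(records["nearest_gene"]).to_numpy()

    io.write_tsv(outdir / "enhancers.tsv", records)
    io.write_bed(
        outdir / "enhancers.bed",
        [
            Interval(r.chromosome, int(r.start), int(r.end), name=r.state)
            for r in records.itertuples(index=False)
        ],
    )
    io.write_json(outdir / "enhancer_summary.json", enh.summarize(records, fc))
    _log(outdir, f"enhancers: {len(records)} records classified")


def stage_promoters(cfg: PipelineConfig, outdir: Path) -> None:
    layout = _load_layout(outdir)
    genes = _load_genes(outdir)
    peaks = {
        c: io.read_bed(
            _require(outdir / "peaks" / f"MYC_{c}.bed", "chip"), f"MYC_{c}"
        )
        for c in CONDITIONS
    }
    bound_by_cond = prom.myc_bound_promoters(peaks, genes)
    bound = set().union(*bound_by_cond.values())
    fc = io.read_tsv(_require(outdir / "fc_MYC_vs_WT.tsv", "expression"), index_col=0)
    records = prom.classify_targets(bound, fc)
    myc_track = _load_track(outdir, layout, "MYC", "MYC")
    miz1_track = _load_track(outdir, layout, "MIZ1", "MYC")
    records = prom.myc_miz1_ratio(records, genes, myc_track, miz1_track)
    io.write_tsv(outdir / "promoters.tsv", records)
    up = records[records["expression_class"] == "up"]["myc_miz1_ratio"]
    down = records[records["expression_class"] == "down"]["myc_miz1_ratio"]
    if len(up) and len(down):
        test = prom.compare_ratio_distributions(up, down)
    else:
        test = {"note": "one of the classes is empty"}
    io.write_json(outdir / "ratio_test.json", test)
    _log(outdir, f"promoters: {len(records)} MYC-bound promoters")


def stage_motifs(cfg: PipelineConfig, outdir: Path) -> None:
    layout = _load_layout(outdir)
    sequences = io.read_fasta(_require(outdir / "sequences.fa", "simulate"))
    records = io.read_tsv(_require(outdir / "enhancers.tsv", "enhancers"))

    def windows_of(df: pd.DataFrame) -> list[str]:
        ivs = [
            Interval(r.chromosome, int(r.start), int(r.end))
            for r in df.itertuples(index=False)
        ]
        wins = mot.extract_center_windows(ivs, layout.lengths, flank=cfg.motif_flank)
        return mot.window_sequences(wins, sequences)

    de_novo = records[records["state"] == "m2_de_novo"]
    gained = de_novo[de_novo["myc_gained_m2"] == 1]
    not_gained = de_novo[de_novo["myc_gained_m2"] == 0]
    background = records[records["state"] == "inactive"]

    rows = []
    bg_seqs = windows_of(background) if len(background) else []
    for pwm_name in ("ebox_canonical", "ebox_noncanonical"):
        pwm = mot.bundled_pwm(pwm_name)
        for label, df in (
            ("denovo_myc_gained", gained),
            ("denovo_not_gained", not_gained),
        ):
            if not len(df) or not bg_seqs:
                continue
            res = mot.enrichment(windows_of(df), bg_seqs, pwm)
            res["target_set"] = label
            rows.append(res)
    io.write_tsv(outdir / "motif_enrichment.tsv", pd.DataFrame(rows))
    _log(outdir, "motifs: enrichment at enhancer centers")


def stage_survival(cfg: PipelineConfig, outdir: Path) -> None:
    expr_df = io.read_tsv(
        _require(outdir / "cohort_expression.tsv", "simulate"), index_col=0
    )
    meta = io.read_tsv(_require(outdir / "cohort_meta.tsv", "simulate")).set_index(
        "sample"
    )
    gene_sets = io.read_gmt(_require(outdir / "genesets.gmt", "simulate"))
    signature = gene_sets["myc_direct_targets"]

    scores = surv.signature_score(expr_df, signature)
    classes = surv.classify(scores)
    scored = meta.copy()
    scored["score"] = scores
    scored["class"] = classes
    io.write_tsv(outdir / "cohort_scored.tsv", scored.rename_axis("sample").reset_index())

    averages = surv.subgroup_average(expr_df, signature, meta["subtype"])
    io.write_tsv(
        outdir / "subgroup_averages.tsv",
        averages.rename_axis("subtype").reset_index(),
    )

    high = scored[scored["class"] == "High"]
    low = scored[scored["class"] == "Low"]
    result = surv.logrank(
        high["time"], high["event"], low["time"], low["event"]
    )
    km = {
        label: surv.km_estimate(sub["time"], sub["event"]).to_dict(orient="list")
        for label, sub in (("High", high), ("Low", low))
    }
    io.write_json(
        outdir / "survival.json",
        {
            "n_high": int(len(high)),
            "n_low": int(len(low)),
            "logrank": result,
            "km": km,
        },
    )
    _log(outdir, f"survival: logrank p={result['p_value']:.3g}")


def stage_report(cfg: PipelineConfig, outdir: Path) -> None:
    report: dict = {"seed": cfg.seed}
    summary = io.read_json(_require(outdir / "enhancer_summary.json", "enhancers"))
    report["enhancer_states"] = {
        s: e["count"] for s, e in summary["states"].items()
    }
    report["median_fc_myc_gained"] = summary.get("median_fc_myc_gained")
    report["median_fc_not_gained"] = summary.get("median_fc_not_gained")
    report["ratio_test"] = io.read_json(_require(outdir / "ratio_test.json", "promoters"))
    report["gsea"] = io.read_json(_require(outdir / "gsea.json", "expression"))
    motif_path = _require(outdir / "motif_enrichment.tsv", "motifs")
    motif_df = io.read_tsv(motif_path)
    report["motif_enrichment"] = motif_df.to_dict(orient="records")
    survival = io.read_json(_require(outdir / "survival.json", "survival"))
    report["logrank"] = survival["logrank"]
    report["n_high"] = survival["n_high"]
    report["n_low"] = survival["n_low"]
    io.write_json(outdir / "report.json", report)
    _log(outdir, "report written")


STAGES = {
    "simulate": stage_simulate,
    "chip": stage_chip,
    "expression": stage_expression,
    "enhancers": stage_enhancers,
    "promoters": stage_promoters,
    "motifs": stage_motifs,
    "survival": stage_survival,
    "report": stage_report,
}

ALL_ORDER = (
    "simulate",
    "chip",
    "expression",
    "enhancers",
    "promoters",
    "motifs",
    "survival",
    "report",
)


def run_all(cfg: PipelineConfig, outdir: Path) -> None:
    for name in ALL_ORDER:
        STAGES[name](cfg, outdir)
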