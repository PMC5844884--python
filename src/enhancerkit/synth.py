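"""Synthetic study generator with planted ground truth.

Emulates the full experimental design on which the analysis modules
operate: three cell states (WT, MYC-overexpressing, M2 mammospheres),
ChIP tag tracks for five targets (MYC, MIZ1, H3K4me1, H3K27ac, H3K4me3)
with Poisson bin counts and planted enriched regions, a triplicate
microarray-style expression matrix whose fold changes are tied to the
planted enhancer/promoter classes, DNA sequence with planted E-box
instances, and a patient cohort whose metastasis hazard depends on the
planted signature class.

Everything is driven by integer seeds through ``numpy.random.Generator``
(PCG64): a fixed seed gives byte-identical outputs across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .genome import CONDITIONS, MARKS, PROMOTER_WINDOW, GeneModel, GenomeLayout
from .intervals import Interval, RegionSet, merge
from .motifs import PWM, bundled_pwm
from .survival import SurvivalCohort
from .tracks import TagTrack

ENHANCER_STATES = (
    "m2_de_novo",
    "wt_active_repressed",
    "unchanged_active",
    "inactive",
)

#: Gene slot pitch (bp): TSSs are placed on a grid of this pitch with
#: jitter, guaranteeing >= 20 kb pairwise separation.
_SLOT = 30_000
_MARGIN = 20_000
_JITTER = 8_000


# ---------------------------------------------------------------------------
# annotation


def default_layout(n_genes: int, bin_width: int = 100, n_chromosomes: int = 2) -> GenomeLayout:
    """A layout just large enough for ``n_genes`` on the slot grid."""
    per_chrom = -(-n_genes // n_chromosomes)
    length = 2 * _MARGIN + per_chrom * _SLOT
    return GenomeLayout(
        {f"chr{i + 1}": length for i in range(n_chromosomes)}, bin_width
    )


def generate_annotation(
    n_genes: int, layout: GenomeLayout, seed: int
) -> list[GeneModel]:
    """Place gene models on the slot grid with >= 20 kb TSS separation.

    Deterministic for a fixed seed; raises if the layout cannot hold the
    requested number of genes.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    capacity = {
        c: max(0, (layout.lengths[c] - 2 * _MARGIN) // _SLOT)
        for c in layout.chromosomes
    }
    if sum(capacity.values()) < n_genes:
        raise ValueError(
            f"layout holds at most {sum(capacity.values())} genes, requested {n_genes}"
        )
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5EED]))
    genes: list[GeneModel] = []
    remaining = n_genes
    idx = 0
    for chrom in layout.chromosomes:
        take = min(capacity[chrom], remaining)
        for slot in range(take):
            tss = _MARGIN + slot * _SLOT + int(rng.integers(0, _JITTER))
            strand = "+" if rng.random() < 0.5 else "-"
            gene_len = int(rng.integers(3000, 8000))
            n_exons = int(rng.integers(2, 6))
            # 2*n_exons offsets within [0, gene_len], first 0, last gene_len
            inner = np.sort(rng.choice(
                np.arange(1, gene_len), size=2 * n_exons - 2, replace=False
            ))
            offsets = np.concatenate(([0], inner, [gene_len]))
            pairs = [
                (int(offsets[2 * i]), int(offsets[2 * i + 1]))
                for i in range(n_exons)
            ]
            if strand == "+":
                exons = tuple((tss + a, tss + b) for a, b in pairs)
            else:
                exons = tuple(sorted((tss - b, tss - a) for a, b in pairs))
            genes.append(
                GeneModel(f"g{idx:04d}", chrom, strand, tss, exons)
            )
            idx += 1
        remaining -= take
        if remaining == 0:
            break
    return genes


# ---------------------------------------------------------------------------
# planted truth


@dataclass
class PlantedTruth:
    """Ground truth planted into every simulated data layer."""

    enhancers: pd.DataFrame  # chromosome, start, end, state, target_gene,
    #                          myc_gained, motif
    promoter_class: pd.Series  # gene -> myc_up | myc_down | unbound
    expr_log2fc: pd.DataFrame  # genes x conditions, log2 FC vs WT baseline
    undetected: list[str]
    rate_ratio: pd.Series  # gene -> true MYC/MIZ1 rate ratio (bound genes)
    hazard_ratio: float
    signature: list[str] = field(default_factory=list)

    def enhancer_regions(self, state: str | None = None) -> list[Interval]:
        df = self.enhancers
        if state is not None:
            df = df[df["state"] == state]
        return [
            Interval(r.chromosome, int(r.start), int(r.end), name=r.target_gene)
            for r in df.itertuples(index=False)
        ]

    def to_dict(self) -> dict:
        return {
            "enhancers": self.enhancers.to_dict(orient="list"),
            "promoter_class": self.promoter_class.to_dict(),
            "expr_log2fc": {
                "index": list(self.expr_log2fc.index),
                "columns": list(self.expr_log2fc.columns),
                "data": self.expr_log2fc.to_numpy().tolist(),
            },
            "undetected": list(self.undetected),
            "rate_ratio": self.rate_ratio.to_dict(),
            "hazard_ratio": self.hazard_ratio,
            "signature": list(self.signature),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PlantedTruth":
        fc = d["expr_log2fc"]
        return cls(
            enhancers=pd.DataFrame(d["enhancers"]),
            promoter_class=pd.Series(d["promoter_class"]),
            expr_log2fc=pd.DataFrame(
                fc["data"], index=fc["index"], columns=fc["columns"]
            ),
            undetected=list(d["undetected"]),
            rate_ratio=pd.Series(d["rate_ratio"], dtype=float),
            hazard_ratio=float(d["hazard_ratio"]),
            signature=list(d["signature"]),
        )


def plant_truth(
    genes: list[GeneModel],
    layout: GenomeLayout,
    seed: int,
    n_per_state: int = 200,
    n_up: int = 120,
    n_down: int = 120,
    n_undetected: int = 60,
    enhancer_width: int = 2000,
    up_fc: float = 4.0,
    down_fc: float = 0.25,
    denovo_gained_fc: float = 4.0,
    denovo_other_fc: float = 1.5,
    rate_ratio_up: float = 8.0,
    rate_ratio_down: float = 0.5,
    hazard_ratio: float = 3.0,
) -> PlantedTruth:
    """Assign genes to planted classes and position planted enhancers.

    Each planted enhancer is hosted by a dedicated gene and centered
    4-8 kb from its TSS, far enough to be distal (> 2 kb from every TSS)
    and close enough that the host is its nearest gene on the slot grid.
    Half of the de novo enhancers additionally gain MYC binding in M2
    and carry a planted E-box instance; myc_down promoters carry MIZ1
    (true MYC/MIZ1 rate ratio below the myc_up promoters').
    """
    need = 4 * n_per_state + n_up + n_down + n_undetected
    if need > len(genes):
        raise ValueError(f"need {need} genes for the requested truth, have {len(genes)}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x7287]))
    order = rng.permutation(len(genes))
    cursor = 0

    def take(n: int) -> list[GeneModel]:
        nonlocal cursor
        out = [genes[i] for i in order[cursor : cursor + n]]
        cursor += n
        return out

    bw = layout.bin_width
    rows = []
    for state in ENHANCER_STATES:
        hosts = take(n_per_state)
        for j, g in enumerate(hosts):
            offset = 5000 + int(rng.integers(0, 3000))
            mid = g.tss + offset
            start = ((mid - enhancer_width // 2) // bw) * bw
            end = start + enhancer_width
            gained = state == "m2_de_novo" and j % 2 == 0
            rows.append(
                {
                    "chromosome": g.chromosome,
                    "start": int(start),
                    "end": int(end),
                    "state": state,
                    "target_gene": g.gene_id,
                    "myc_gained": int(gained),
                    "motif": int(gained),
                }
            )
    enhancers = pd.DataFrame(
        rows,
        columns=[
            "chromosome", "start", "end", "state", "target_gene", "myc_gained",
            "motif",
        ],
    )

    up_genes = take(n_up)
    down_genes = take(n_down)
    undetected = [g.gene_id for g in take(n_undetected)]

    promoter_class = pd.Series("unbound", index=[g.gene_id for g in genes])
    promoter_class[[g.gene_id for g in up_genes]] = "myc_up"
    promoter_class[[g.gene_id for g in down_genes]] = "myc_down"

    fc = pd.DataFrame(
        0.0, index=[g.gene_id for g in genes], columns=list(CONDITIONS)
    )
    fc.loc[[g.gene_id for g in up_genes], ["MYC", "M2"]] = np.log2(up_fc)
    fc.loc[[g.gene_id for g in down_genes], ["MYC", "M2"]] = np.log2(down_fc)
    dn = enhancers[enhancers["state"] == "m2_de_novo"]
    fc.loc[dn[dn["myc_gained"] == 1]["target_gene"], "M2"] += np.log2(denovo_gained_fc)
    fc.loc[dn[dn["myc_gained"] == 0]["target_gene"], "M2"] += np.log2(denovo_other_fc)

    rate_ratio = pd.Series(
        {
            **{g.gene_id: rate_ratio_up for g in up_genes},
            **{g.gene_id: rate_ratio_down for g in down_genes},
        },
        dtype=float,
    )
    return PlantedTruth(
        enhancers=enhancers,
        promoter_class=promoter_class,
        expr_log2fc=fc,
        undetected=undetected,
        rate_ratio=rate_ratio,
        hazard_ratio=float(hazard_ratio),
        signature=sorted(g.gene_id for g in up_genes),
    )


# ---------------------------------------------------------------------------
# ChIP tracks


def default_fold_map(base_fold: float = 8.0) -> dict:
    """Per-mark, per-state enrichment folds for each condition.

    MYC occupancy at up-promoters is higher than at down-promoters and
    rises with overexpression; MIZ1 dominates at down-promoters so the
    true MYC/MIZ1 rate ratio is 8 (up) vs 0.5 (down) in the MYC state.
    """
    b = base_fold
    all3 = {"WT": b, "MYC": b, "M2": b}
    return {
        "H3K4me1": {
            "wt_active_repressed": dict(all3),
            "unchanged_active": dict(all3),
            "inactive": dict(all3),
            "m2_de_novo": {"M2": b},
        },
        "H3K27ac": {
            "wt_active_repressed": {"WT": b},
            "unchanged_active": dict(all3),
            "m2_de_novo": {"M2": b},
        },
        "MYC": {
            "myc_up": {"WT": b, "MYC": 2 * b, "M2": 2 * b},
            "myc_down": {"WT": b / 2, "MYC": b / 2, "M2": b / 2},
            "m2_de_novo_gained": {"M2": b},
        },
        "MIZ1": {
            "myc_up": {"WT": b / 4, "MYC": b / 4, "M2": b / 4},
            "myc_down": {"WT": b, "MYC": b, "M2": b},
        },
        "H3K4me3": {"active_promoter": dict(all3)},
    }


def _validate_fold_map(fold_map: dict) -> None:
    for mark, states in fold_map.items():
        for state, conds in states.items():
            for cond, fold in conds.items():
                if fold < 1:
                    raise ValueError(
                        f"fold must be >= 1 ({mark}/{state}/{cond} = {fold})"
                    )


@dataclass
class SimulatedChip:
    """Tag tracks plus the true enriched-region sets that produced them."""

    tracks: dict[tuple[str, str], TagTrack]  # (mark, condition) -> track
    true_regions: dict[tuple[str, str], RegionSet]


def _promoter_region(g: GeneModel) -> Interval:
    s, e = g.promoter(PROMOTER_WINDOW)
    return Interval(g.chromosome, max(0, s), e)


def simulate_chip(
    genes: list[GeneModel],
    truth: PlantedTruth,
    layout: GenomeLayout,
    depth: float | None = 2_000_000,
    background_rate: float = 2.0,
    fold_map: dict | None = None,
    seed: int = 0,
) -> SimulatedChip:
    """Poisson bin-count tracks for all marks x conditions.

    Bin counts are independent Poisson draws with mean background_rate
    outside planted regions and background_rate x fold inside; when
    ``depth`` is given the rate profile is rescaled so its expected
    total equals depth (the recorded library size is the realized sum).
    """
    if depth is not None and depth <= 0:
        raise ValueError("depth must be positive")
    if background_rate <= 0:
        raise ValueError("background_rate must be positive")
    fold_map = default_fold_map() if fold_map is None else fold_map
    _validate_fold_map(fold_map)

    gene_map = {g.gene_id: g for g in genes}
    detected = set(truth.expr_log2fc.index) - set(truth.undetected)

    # (mark, cond) -> list of (Interval, fold)
    enriched: dict[tuple[str, str], list[tuple[Interval, float]]] = {
        (m, c): [] for m in MARKS for c in CONDITIONS
    }

    for row in truth.enhancers.itertuples(index=False):
        iv = Interval(row.chromosome, int(row.start), int(row.end))
        for mark in ("H3K4me1", "H3K27ac"):
            for cond, fold in fold_map.get(mark, {}).get(row.state, {}).items():
                enriched[(mark, cond)].append((iv, fold))
        if row.myc_gained:
            for cond, fold in (
                fold_map.get("MYC", {}).get("m2_de_novo_gained", {}).items()
            ):
                enriched[("MYC", cond)].append((iv, fold))

    for gene_id, cls in truth.promoter_class.items():
        g = gene_map[gene_id]
        win = _promoter_region(g)
        if cls in ("myc_up", "myc_down"):
            for mark in ("MYC", "MIZ1"):
                for cond, fold in fold_map.get(mark, {}).get(cls, {}).items():
                    enriched[(mark, cond)].append((win, fold))
        if gene_id in detected:
            for cond, fold in (
                fold_map.get("H3K4me3", {}).get("active_promoter", {}).items()
            ):
                enriched[("H3K4me3", cond)].append((win, fold))

    ss = np.random.SeedSequence([seed, 0xC41B])
    children = ss.spawn(len(MARKS) * len(CONDITIONS))
    tracks: dict[tuple[str, str], TagTrack] = {}
    true_regions: dict[tuple[str, str], RegionSet] = {}
    bw = layout.bin_width
    i = 0
    for mark in MARKS:
        for cond in CONDITIONS:
            rng = np.random.default_rng(children[i])
            i += 1
            rates = {
                c: np.full(layout.n_bins(c), background_rate, dtype=float)
                for c in layout.chromosomes
            }
            for iv, fold in enriched[(mark, cond)]:
                lo = iv.start // bw
                hi = -(-iv.end // bw)
                rates[iv.chromosome][lo:hi] *= fold
            if depth is not None:
                total = sum(a.sum() for a in rates.values())
                scale = depth / total
                for a in rates.values():
                    a *= scale
            counts = {c: rng.poisson(a) for c, a in rates.items()}
            tracks[(mark, cond)] = TagTrack.from_counts(counts, bw)
            true_regions[(mark, cond)] = merge(
                [iv for iv, _ in enriched[(mark, cond)]],
                label=f"{mark}_{cond}",
            )
    return SimulatedChip(tracks, true_regions)


# ---------------------------------------------------------------------------
# expression


def simulate_expression(
    genes: list[GeneModel],
    truth: PlantedTruth,
    n_reps: int = 3,
    noise_sd: float = 0.25,
    seed: int = 0,
    baseline_range: tuple[float, float] = (4.0, 9.0),
) -> ExpressionMatrix:
    """Triplicate microarray-style intensities with planted fold changes.

    log2 intensity = gene baseline + planted log2 FC of the condition +
    Gaussian noise(noise_sd). Detection p-values are ~0 for expressed
    genes and > 0.05 in all samples for the planted undetected subset.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xE784]))
    gene_ids = [g.gene_id for g in genes]
    undetected = set(truth.undetected)
    lo, hi = baseline_range
    baseline = pd.Series(rng.uniform(lo, hi, size=len(gene_ids)), index=gene_ids)
    und = sorted(undetected & set(gene_ids))
    baseline[und] = rng.uniform(-2.0, -1.0, size=len(und))
    samples = [f"{c}_{r + 1}" for c in CONDITIONS for r in range(n_reps)]
    conditions = pd.Series(
        {s: s.rsplit("_", 1)[0] for s in samples}, name="condition"
    )
    log2 = pd.DataFrame(index=gene_ids, columns=samples, dtype=float)
    for s in samples:
        cond = conditions[s]
        noise = rng.normal(0.0, noise_sd, size=len(gene_ids)) if noise_sd > 0 else 0.0
        log2[s] = (
            baseline.to_numpy()
            + truth.expr_log2fc.reindex(gene_ids)[cond].fillna(0.0).to_numpy()
            + noise
        )
    intensities = 2.0 ** log2
    det = pd.DataFrame(index=gene_ids, columns=samples, dtype=float)
    for s in samples:
        det[s] = rng.uniform(0.0, 0.01, size=len(gene_ids))
        mask = [g in undetected for g in gene_ids]
        det.loc[mask, s] = rng.uniform(0.06, 0.5, size=sum(mask))
    return ExpressionMatrix(intensities, det, conditions)


# ---------------------------------------------------------------------------
# sequence


def simulate_sequences(
    layout: GenomeLayout,
    truth: PlantedTruth,
    seed: int = 0,
    motif_pwm: PWM | None = None,
) -> dict[str, str]:
    """Uniform-random chromosome sequences with planted motif instances.

    The motif consensus is written at the center of every motif-bearing
    planted enhancer (MYC-gained de novo enhancers by default).
    """
    pwm = motif_pwm if motif_pwm is not None else bundled_pwm("ebox_noncanonical")
    consensus = pwm.consensus()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5EC5]))
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    seqs: dict[str, bytearray] = {}
    for chrom in layout.chromosomes:
        arr = bases[rng.integers(0, 4, size=layout.lengths[chrom])]
        seqs[chrom] = bytearray(arr.tobytes())
    planted = truth.enhancers[truth.enhancers["motif"] == 1]
    for row in planted.itertuples(index=False):
        mid = (int(row.start) + int(row.end)) // 2
        s = mid - len(consensus) // 2
        seqs[row.chromosome][s : s + len(consensus)] = consensus.encode("ascii")
    return {c: b.decode("ascii") for c, b in seqs.items()}


# ---------------------------------------------------------------------------
# cohort


@dataclass
class SimulatedCohort:
    cohort: SurvivalCohort
    true_group: pd.Series  # sample -> High | Low (planted)


def simulate_cohort(
    signature: list[str],
    n_patients: int = 300,
    hazard_ratio: float = 3.0,
    censor_fraction: float = 0.3,
    seed: int = 0,
    effect_size: float = 1.0,
    n_noise_genes: int = 50,
    base_median_months: float = 60.0,
) -> SimulatedCohort:
    """Patient cohort whose metastasis hazard depends on signature class.

    Half the patients are planted signature-High: their signature-gene
    expression is shifted by +effect_size standard deviations (Low:
    -effect_size), so the sign of the true score defines the groups.
    Event times are exponential with a hazard ``hazard_ratio``-fold
    higher for the High group; censoring strikes each patient
    independently with probability ``censor_fraction``. Molecular
    subtype labels are drawn with basal-like enriched among High
    patients.
    """
    if not signature:
        raise ValueError("signature must be non-empty")
    if hazard_ratio <= 0:
        raise ValueError("hazard_ratio must be positive")
    if not (0 <= censor_fraction < 1):
        raise ValueError("censor_fraction must lie in [0, 1)")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC0F0]))
    samples = [f"P{i + 1:04d}" for i in range(n_patients)]
    high = rng.random(n_patients) < 0.5
    shift = np.where(high, effect_size, -effect_size)

    sig = sorted(set(signature))
    noise_genes = [f"noise{i:03d}" for i in range(n_noise_genes)]
    expr = pd.DataFrame(
        rng.normal(0.0, 1.0, size=(len(sig) + n_noise_genes, n_patients)),
        index=sig + noise_genes,
        columns=samples,
    )
    expr.loc[sig] += shift[np.newaxis, :]

    rate_low = np.log(2.0) / base_median_months
    rates = np.where(high, rate_low * hazard_ratio, rate_low)
    event_times = rng.exponential(1.0 / rates)
    censored = rng.random(n_patients) < censor_fraction
    u = rng.uniform(1e-6, 1.0, size=n_patients)
    times = np.where(censored, event_times * u, event_times)
    events = (~censored).astype(int)

    subtypes = np.array(["luminal_a", "luminal_b", "her2", "basal", "normal_like"])
    p_high = np.array([0.10, 0.15, 0.15, 0.50, 0.10])
    p_low = np.array([0.40, 0.20, 0.15, 0.10, 0.15])
    labels = [
        subtypes[rng.choice(5, p=p_high if h else p_low)] for h in high
    ]
    meta = pd.DataFrame(
        {"time": times, "event": events, "subtype": labels}, index=samples
    )
    cohort = SurvivalCohort(expr, meta)
    return SimulatedCohort(
        cohort, pd.Series(np.where(high, "High", "Low"), index=samples)
    )


# ---------------------------------------------------------------------------
# whole-study bundle


@dataclass
class StudyParams:
    """Default study conditions for the end-to-end synthetic dataset."""

    n_per_state: int = 200
    n_up: int = 120
    n_down: int = 120
    n_undetected: int = 60
    bin_width: int = 100
    depth: float = 2_000_000
    background_rate: float = 2.0
    base_fold: float = 8.0
    n_reps: int = 3
    noise_sd: float = 0.25
    n_patients: int = 300
    hazard_ratio: float = 3.0
    censor_fraction: float = 0.3

    @property
    def n_genes(self) -> int:
        return 4 * self.n_per_state + self.n_up + self.n_down + self.n_undetected


@dataclass
class SyntheticStudy:
    layout: GenomeLayout
    genes: list[GeneModel]
    truth: PlantedTruth
    chip: SimulatedChip
    expression: ExpressionMatrix
    cohort: SimulatedCohort
    gene_sets: dict[str, list[str]]


def simulate_study(params: StudyParams | None = None, seed: int = 0) -> SyntheticStudy:
    """Generate the complete synthetic study (tracks, expression, cohort)."""
    p = params or StudyParams()
    layout = default_layout(p.n_genes, p.bin_width)
    genes = generate_annotation(p.n_genes, layout, seed)
    truth = plant_truth(
        genes,
        layout,
        seed,
        n_per_state=p.n_per_state,
        n_up=p.n_up,
        n_down=p.n_down,
        n_undetected=p.n_undetected,
        hazard_ratio=p.hazard_ratio,
    )
    chip = simulate_chip(
        genes,
        truth,
        layout,
        depth=p.depth,
        background_rate=p.background_rate,
        fold_map=default_fold_map(p.base_fold),
        seed=seed,
    )
    expression = simulate_expression(
        genes, truth, n_reps=p.n_reps, noise_sd=p.noise_sd, seed=seed
    )
    cohort = simulate_cohort(
        truth.signature,
        n_patients=p.n_patients,
        hazard_ratio=p.hazard_ratio,
        censor_fraction=p.censor_fraction,
        seed=seed,
    )
    dn = truth.enhancers[truth.enhancers["state"] == "m2_de_novo"]
    gene_sets = {
        "myc_direct_targets": list(truth.signature),
        "myc_repressed_targets": sorted(
            truth.promoter_class[truth.promoter_class == "myc_down"].index
        ),
        "denovo_enhancer_targets": sorted(dn["target_gene"]),
    }
    return SyntheticStudy(layout, genes, truth, chip, expression, cohort, gene_sets)
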