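# enhancerkit

Chromatin-state and transcriptome inference for a three-state cellular
reprogramming design, exercised end to end on synthetic data with
planted ground truth.

## The problem

When MYC is overexpressed in immortalized mammary epithelial cells and
the cells transition to a stem-like mammosphere state (M2), the
enhancer landscape is rewritten: some active enhancers are
decommissioned, others stay active, and a class of **de novo
enhancers** — regions carrying neither H3K4me1 nor H3K27ac in either
parental state — gains both marks only in M2. At promoters, MYC binds
two transcriptionally opposite target subsets, and the **MYC/MIZ1
occupancy ratio** separates them: a high ratio marks directly activated
genes, a low ratio marks MIZ1-co-bound repressed genes. A zero-mean
**MYC direct-target signature score** dichotomizes patient cohorts into
High/Low groups with different metastasis-free survival.

`enhancerkit` implements this analysis chain as a tested library + CLI:

| stage | what it does |
|---|---|
| `synth` | generates every input (annotation, Poisson tag tracks for MYC/MIZ1/H3K4me1/H3K27ac/H3K4me3 × WT/MYC/M2, triplicate expression, DNA sequence with planted E-boxes, patient cohort) with known planted truth |
| `intervals` | merge, three-way overlap partition with membership bits, nearest-TSS annotation (promoter/exon/intron/intergenic) |
| `enrichment` | RPM normalization; sharp-peak calling (Poisson tail, p < 1e-6); broad-domain calling (200-bp windows, 200-bp gap, BH FDR < 0.01); differential regions (twofold + one-sided Poisson p < 1e-4, counts scaled to the smaller library) |
| `enhancers` | distal H3K4me1 regions → H3K27ac activity bits per state → labels: `wt_active_repressed`, `unchanged_active`, `m2_de_novo`, `other_modulated`, `inactive`; split of de novo enhancers by MYC binding gain in M2 |
| `promoters` | MYC-bound promoters, up/down expression classes, MYC/MIZ1 RPM ratio with rank-sum comparison |
| `expression` | quantile normalization, detection-p filter (p > 0.05 in all samples), flooring at 1, twofold calls, preranked GSEA (weighted KS running sum, gene-set permutation), bin-of-ten binding–expression correlation |
| `motifs` | log-odds PWM scanning of enhancer-center ±2 kb windows, window-level Fisher enrichment (canonical/non-canonical E-box matrices included) |
| `survival` | zero-mean signature score, High/Low classification, subtype subgroup averages, Kaplan–Meier curves and log-rank (Mantel–Cox) test |

The core statistics, in the field's notation: bin counts are modeled as
X ~ Poisson(λ), window significance is the one-sided tail
P(X ≥ k | λ = genome-wide rate); differential enrichment of region
counts a vs b uses fold = (a′+1)/(b′+1) and P(X ≥ a′ | λ = b′+1) after
scaling to the smaller library (an exact conditional binomial p is also
reported); the GSEA score is the signed maximum deviation of the
weighted Kolmogorov–Smirnov running sum; the signature score is the
re-centered mean of gene-wise z-scores; High/Low survival is compared
with the Mantel–Cox statistic (O−E)²/V ~ χ²(1).

## Worked example

```python
from enhancerkit.synth import StudyParams, simulate_study
from enhancerkit.enrichment import call_broad_domains
from enhancerkit.enhancers import (putative_enhancers, classify_states,
                                   assign_target_genes, summarize)
from enhancerkit.expression import (quantile_normalize, detection_filter,
                                    fold_change_calls)

study = simulate_study(StudyParams(n_per_state=50, n_up=40, n_down=40,
                                   n_undetected=10), seed=7)
k4 = {c: call_broad_domains(study.chip.tracks[("H3K4me1", c)])
      for c in ("WT", "MYC", "M2")}
k27 = {c: call_broad_domains(study.chip.tracks[("H3K27ac", c)])
       for c in ("WT", "MYC", "M2")}
records = assign_target_genes(
    classify_states(putative_enhancers(k4, study.genes), k27), study.genes)
print(records["state"].value_counts())

norm = detection_filter(quantile_normalize(study.expression.intensities),
                        study.expression.detection_p)
fc = fold_change_calls(norm, "MYC", "M2", study.expression.conditions)
s = summarize(records, fc["fold_change"])
print("de novo mean span (bp):", round(s["states"]["m2_de_novo"]["mean_span_bp"], 1))
print("median FC (M2 vs MYC) at de novo targets:",
      round(s["states"]["m2_de_novo"]["median_expression_fc"], 2))
```

prints

```
state
wt_active_repressed    50
unchanged_active       50
inactive               50
m2_de_novo             50
Name: count, dtype: int64
de novo mean span (bp): 2104.0
median FC (M2 vs MYC) at de novo targets: 1.76
```

All 200 planted enhancers (50 per state) are recovered with their
planted labels; the recovered de novo regions span ~2.1 kb (2-kb
planted regions plus partial boundary windows), and the genes assigned
to de novo enhancers are transcriptionally induced in M2 (median
fold change 1.76 over all de novo targets — the MYC-gained half is
planted at fold 4, the rest at 1.5, and quantile normalization
compresses extreme ratios slightly).

The same chain runs from the shell:

```bash
enhancerkit all --seed 1 --outdir run1   # simulate → ... → report
cat run1/report.json
```

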