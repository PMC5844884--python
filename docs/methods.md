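# Methods

This note documents the generative model behind the synthetic study,
the statistical procedures of each analysis stage, the numerical
conventions, and the limits of what the synthetic design can show.

## Study design being emulated

Three cell states are profiled: parental immortalized mammary
epithelial cells (WT), the same cells overexpressing MYC (MYC), and
single-cell-derived secondary mammospheres (M2, the stem-like state).
Five ChIP targets are tracked per state — MYC, MIZ1, H3K4me1 (primed
enhancers), H3K27ac (active enhancers/promoters), H3K4me3 (active
promoters) — together with a triplicate expression profile per state
and, separately, a breast-cancer cohort with metastasis-free follow-up
and molecular subtype labels.

## Synthetic data generator

**Genome and genes.** Chromosome coordinates are 0-based half-open;
tracks are binned at 100 bp (last bin may be partial). Gene TSSs sit on
a 30-kb grid with up to 8 kb of jitter, guaranteeing ≥ 20 kb pairwise
TSS separation so promoter/distal assignments are unambiguous. Genes
have 2–5 exons over a 3–8 kb body; the TSS equals the 5′ exon boundary
on the gene strand.

**Planted truth.** Each planted enhancer (2 kb, bin-aligned) is hosted
by a dedicated gene, centered 5–8 kb from its TSS — distal (> 2 kb from
every TSS) yet unambiguously nearest to its host. Four states are
planted in equal numbers (default 200 each):

| state | H3K4me1 (WT/MYC/M2) | H3K27ac (WT/MYC/M2) |
|---|---|---|
| `wt_active_repressed` | ✓ ✓ ✓ | ✓ · · |
| `unchanged_active`    | ✓ ✓ ✓ | ✓ ✓ ✓ |
| `m2_de_novo`          | · · ✓ | · · ✓ |
| `inactive`            | ✓ ✓ ✓ | · · · |

Half of the de novo enhancers additionally gain MYC binding in M2 and
carry a planted non-canonical E-box at their center; their target genes
are induced fourfold in M2 vs MYC (the other half: 1.5-fold). Promoter
classes: 120 `myc_up` genes (fourfold induced on MYC overexpression,
MYC enrichment 8× in WT rising to 16×, MIZ1 2×; true MYC/MIZ1 rate
ratio 8) and 120 `myc_down` genes (fourfold repressed, MYC 4×, MIZ1 8×;
ratio 0.5). H3K4me3 marks the promoters of all detected genes. A
60-gene subset is planted as undetected (detection p > 0.05 in every
sample).

**Tag tracks.** Bin counts are independent Poisson draws: mean =
background rate outside planted regions, background × fold inside.
`background_rate` (default 2 tags/bin) shapes the rate profile;
the profile is then rescaled so its expected total equals `depth`
(default 2 × 10⁶ tags per track), and the recorded library size is the
realized Poisson total — within 1% of the requested depth at default
scale. Poisson bin counts were chosen to match the Poisson enrichment
tests downstream; planted regions are bin-aligned to avoid partial-bin
edge effects.

**Expression.** log2 intensity = per-gene baseline U(4, 9) + planted
log2 fold change of the condition + N(0, σ), σ = 0.25 by default, three
replicates per state; intensities are 2^log2. Additive Gaussian noise
on the log scale is the standard microarray approximation and keeps
parameter-recovery arithmetic closed-form. Detection p-values are
emitted directly (U(0, 0.01) for detected genes, U(0.06, 0.5) for the
undetected subset) rather than derived from a bead-array error model:
downstream they act only as a filter. Background subtraction is assumed
to have happened upstream (a vendor preprocessing step); the generator
emits already-subtracted intensities.

**Cohort.** Half the patients are planted signature-High (signature
genes shifted +1 SD; Low −1 SD), so the sign of the true score defines
the groups. Event times are exponential with median 60 months for Low
and a hazard `hazard_ratio` (default 3) higher for High. Censoring is a
Bernoulli(censor_fraction) indicator drawn independently of group and
time; a censored patient's observation time is U(0,1) × the latent
event time. Subtype labels are drawn with basal-like enriched among
High patients (50% vs 10%), so the basal subgroup carries the highest
signature average by construction.

**Sequence.** Chromosomes are uniform-random A/C/G/T; the consensus of
the non-canonical E-box matrix is written at the center of every
motif-bearing enhancer. The two bundled E-box matrices
(`data/*.pwm`) are synthetic consensus-derived fixtures — a 10-bp
extended core (GGCACGTGCC / GGCATGTGCC at 0.85 per consensus base) —
not measured binding models; the extension keeps the chance-hit rate of
a ±2 kb window below ~1%, which a bare 6-mer could not.

## Statistical procedures

**Peak calling.** Sharp peaks (MYC, MIZ1): one-sided Poisson tail of
single-bin counts against the genome-wide mean rate, p < 1e-6,
significant bins merged. Broad domains (histone marks): 200-bp tiling
windows, Poisson tails, Benjamini–Hochberg at FDR 0.01, significant
windows joined across gaps ≤ 200 bp; a domain's q is the worst member
q. Both callers are deliberately simplified (no local background, no
fragment-shift model): the biology tested here lives in the downstream
classification, and exact-tail scans keep every p-value verifiable by
direct summation.

**Differential regions.** Counts are scaled to the smaller library;
fold = (a′+1)/(b′+1) with a pseudocount of 1; a region is differential
iff fold ≥ 2 AND the one-sided Poisson tail P(X ≥ a′ | λ = b′+1)
< 1e-4 (direction recorded; the test is exactly antisymmetric in its
arguments). This statistic — the convention of differential-peak
tools — conditions on the scaled reference count as if it were a
noise-free rate. When both tracks are equally shallow that is
anti-conservative (the exact null rejection probability exceeds the
nominal level severalfold for α ≤ 1e-3 at any count scale); it is
near-exact when the reference is much deeper. The results therefore
also carry `p_binomial`, the exact conditional binomial test (given
t = a+b, a ~ Binomial(t, lib_a/(lib_a+lib_b)) under no difference),
which is calibrated — conservatively, because counts are discrete — at
every depth ratio. The twofold-plus-p gate used for the biology is the
published convention; calibration guarantees are stated only for the
conditional form.

**Enhancer construction.** Putative enhancers are the connected
components of the union of the three per-state H3K4me1 domain sets,
each labeled with a membership bit per state (≥ 1 bp overlap), then
restricted to distal components (midpoint > 2 kb from every TSS; 2 kb
is consistent with the ±2 kb center windows used for motifs) with span
≥ 1 kb. The minimum-span filter exists because BH at FDR 0.01 across
~10⁵ windows necessarily admits on the order of 1% of discoveries as
isolated false single windows; genuine primed enhancers are broad,
isolated 200–400 bp islands are sampling noise, and without the filter
they would accumulate in the never-active class. H3K27ac activity in a
state requires both ≥ 1 bp overlap with that state's K27ac domains and
the H3K4me1 bit in the same state (activity presupposes priming).
State labels are total over all bit patterns, with `m2_de_novo`
requiring the strict pattern "no H3K4me1 and no H3K27ac in WT and MYC,
both in M2" — "parental" is read as both IMEC states. Nearest-gene
assignment is by absolute midpoint-to-TSS distance, ties broken by
lexicographic gene id.

**Promoters.** The promoter window is strand-oriented
[TSS − 1000, TSS + 100). A gene is MYC-bound in a state iff its window
overlaps a MYC peak (≥ 1 bp). The MYC/MIZ1 ratio is
(MYC RPM + ε_MYC)/(MIZ1 RPM + ε_MIZ1) over the window in the
MYC-overexpressing state, where ε is the RPM of a single tag in the
respective library — a doubly-empty promoter has ratio exactly 1. The
two expression classes are compared by a two-sided Wilcoxon rank-sum on
log ratios (exact enumeration for small samples via scipy).

**Expression.** Quantile normalization maps every column onto the
rank-wise mean of order statistics; within-column ties receive the mean
of the reference values they span. A gene is discarded iff detection
p > 0.05 in **all** samples. Fold changes are computed on the linear
scale after flooring intensities at 1, as mean(B)/mean(A) over ≥ 2
replicates; calls are up at FC ≥ 2 and down at FC ≤ 0.5 (boundaries
inclusive). GSEA uses the weighted KS running sum (hit increments
|stat|^w normalized to 1, w = 1 by default; miss decrements
1/(N − N_hit)); ES is the extreme deviation, with an exact tie between
the positive and negative extreme resolved positive. The null permutes
gene-set membership, not phenotype labels: with three replicates per
state, phenotype permutation has too few distinct relabelings to be
meaningful. NES divides ES by the mean |permuted ES| of the same sign;
p = (1 + #{as extreme, same sign})/(n_perm + 1). The binding–expression
relation sorts genes by descending fold change (ties by gene id), takes
consecutive bins of 10 (trailing partial bin dropped), and reports the
Pearson r over bin means; zero variance in either vector is flagged
degenerate rather than coerced to a number.

**Motifs.** Scanning is log2-odds against the PWM background on both
strands; a position hits iff the score reaches the threshold (default
80% of the maximum attainable score); any window containing N never
matches. Enrichment is a one-sided Fisher exact test on window-level
presence/absence — the unit used by motif-enrichment tools — not on
hit counts; fold is the ratio of hit fractions (infinite when only
targets hit; 1 when neither does).

**Signature and survival.** Each measured signature gene is z-scored
across samples (population SD; zero-variance genes dropped with a log
entry); a sample's score is the mean over signature genes, re-centered
to make the cohort mean exactly zero — the mean rather than the sum
keeps the score scale-free, and the final re-centering enforces the
zero-mean definition literally. Scores > 0 are High, < 0 Low; an exact
zero is classified Low with a warning (the convention leaves ties
undefined). Subgroup averages standardize across all samples first and
then average within subgroup (adimensional values). Kaplan–Meier and
the Mantel–Cox log-rank test (ties handled by the simultaneous-event
hypergeometric variance) are computed by lifelines; the statistic is
compared to χ²(1), two-sided.

## Reproducibility and problem sizes

All randomness flows through `numpy.random.Generator` (PCG64) seeded
from integer `SeedSequence`s spawned in a fixed order; a fixed seed
yields byte-identical output files (writers emit LF line endings and
deterministic float formatting; the pipeline log carries no
timestamps). The default study uses two ~16.5-Mb chromosomes (330k
bins), 1,100 genes, 200 enhancers per state, 2M tags per track, and a
300-patient cohort — large enough that every planted structure is
recovered essentially perfectly, small enough that the full pipeline
runs in seconds. The test suite's Monte-Carlo checks use 100–300
replicates at reduced genome sizes; the calibration checks use 10,000
null regions/windows.

## What the synthetic design does and does not show

The generator plants clean, bin-aligned, well-separated signals with
homogeneous background: passing tests demonstrate that the inference
chain is correct under its own model (Poisson counts, independent
bins, additive log-normal expression noise, exponential survival). It
does not emulate fragment-length effects, read mappability, copy-number
or chromatin-accessibility background structure, batch effects,
overdispersion (negative-binomial counts), correlated gene expression,
or subtype-dependent hazards beyond the planted group effect. Recovery
rates on real data will be correspondingly lower, and the simplified
peak callers are not drop-in replacements for MACS2/SICER on real
libraries. PAM50-style subtype assignment is out of scope: subtype
labels are an input column. Tag counting is bin-resolution (partial
bins count in full), so region statistics carry up to one bin width of
positional slack at each edge.
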