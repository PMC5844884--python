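"""Microarray-style expression processing and gene-set statistics.

The processing chain mirrors standard bead-array practice: quantile
normalization across samples, removal of genes undetected (detection
p > 0.05) in every sample, flooring of intensities below 1, and twofold
up/down calls on condition means. Gene-set enrichment is the weighted
Kolmogorov–Smirnov running-sum statistic with a gene-set permutation
null; the binding–expression relation is summarized by bins of ten
genes, as in rank-binned correlation plots.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ExpressionMatrix:
    """Intensities (genes x samples), detection p-values, condition map."""

    intensities: pd.DataFrame
    detection_p: pd.DataFrame
    conditions: pd.Series  # sample -> condition label

    def __post_init__(self) -> None:
        if not self.intensities.columns.equals(self.detection_p.columns):
            raise ValueError("intensity and detection tables have different samples")
        if not self.intensities.index.equals(self.detection_p.index):
            raise ValueError("intensity and detection tables have different genes")
        missing = [s for s in self.intensities.columns if s not in self.conditions]
        if missing:
            raise ValueError(f"samples without condition label: {missing}")

    def samples_of(self, condition: str) -> list[str]:
        cols = [s for s in self.intensities.columns if self.conditions[s] == condition]
        if not cols:
            raise KeyError(f"unknown condition {condition!r}")
        return cols


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every sample onto the common (rank-wise mean) distribution.

    After normalization the sorted value vector of every column is
    identical: the across-sample mean of order statistics. Ties within a
    column receive the mean of the reference values their positions span.
    """
    if matrix.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    if matrix.isna().all(axis=0).any():
        raise ValueError("column with all-missing values")
    values = matrix.to_numpy(dtype=float)
    ref = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty_like(ref)
        assigned[order] = ref
        # ties: average the reference values spanned by equal inputs
        out[:, j] = pd.Series(assigned).groupby(col).transform("mean").to_numpy()
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def detection_filter(
    matrix: pd.DataFrame, detection_p: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Drop genes whose detection p exceeds alpha in every sample.

    A single sample with detection p <= alpha keeps the gene.
    """
    if not matrix.index.equals(detection_p.index) or not matrix.columns.equals(
        detection_p.columns
    ):
        raise ValueError("intensity and detection tables are misaligned")
    keep = (detection_p <= alpha).any(axis=1)
    return matrix.loc[keep]


def fold_change_calls(
    matrix: ExpressionMatrix | pd.DataFrame,
    condition_a: str,
    condition_b: str,
    conditions: pd.Series | None = None,
    floor: float = 1.0,
    threshold: float = 2.0,
) -> pd.DataFrame:
    """Per-gene fold change of condition_b over condition_a with calls.

    Intensities below ``floor`` are set to ``floor`` before averaging
    replicates; FC = mean(B)/mean(A); a gene is "up" iff FC >= threshold
    and "down" iff FC <= 1/threshold, else "unchanged".
    """
    if isinstance(matrix, ExpressionMatrix):
        intens, cond = matrix.intensities, matrix.conditions
    else:
        if conditions is None:
            raise ValueError("conditions mapping required with a bare DataFrame")
        intens, cond = matrix, conditions
    cols_a = [s for s in intens.columns if cond[s] == condition_a]
    cols_b = [s for s in intens.columns if cond[s] == condition_b]
    if not cols_a:
        raise KeyError(f"unknown condition {condition_a!r}")
    if not cols_b:
        raise KeyError(f"unknown condition {condition_b!r}")
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("fold-change calls need >= 2 replicates per condition")
    floored = intens.clip(lower=floor)
    mean_a = floored[cols_a].mean(axis=1)
    mean_b = floored[cols_b].mean(axis=1)
    fc = mean_b / mean_a
    call = pd.Series("unchanged", index=fc.index)
    call[fc >= threshold] = "up"
    call[fc <= 1.0 / threshold] = "down"
    return pd.DataFrame(
        {"mean_a": mean_a, "mean_b": mean_b, "fold_change": fc, "call": call}
    )


@dataclass
class EnrichmentScoreResult:
    gene_set: str
    es: float
    nes: float
    p_value: float
    leading_edge: list[str] = field(default_factory=list)


def _running_sum_es(
    ranked_genes: np.ndarray, ranked_stats: np.ndarray, in_set: np.ndarray, weight: float
) -> tuple[float, int]:
    """ES = signed maximum deviation of the weighted KS running sum.

    Returns (ES, index of the extremum in the ranked list).
    """
    n = len(ranked_genes)
    n_hit = int(in_set.sum())
    w = np.abs(ranked_stats) ** weight
    hit_w = np.where(in_set, w, 0.0)
    denom = hit_w.sum()
    if denom == 0:
        hit_w = in_set.astype(float)
        denom = float(n_hit)
    p_hit = np.cumsum(hit_w) / denom
    p_miss = np.cumsum(~in_set) / (n - n_hit)
    dev = p_hit - p_miss
    i_pos = int(np.argmax(dev))
    i_neg = int(np.argmin(dev))
    # exact ties between the positive and negative extreme go positive
    if dev[i_pos] >= -dev[i_neg]:
        return float(dev[i_pos]), i_pos
    return float(dev[i_neg]), i_neg


def enrichment_score(
    ranked_stats: pd.Series,
    gene_set: set[str] | list[str],
    weight: float = 1.0,
) -> float:
    """The enrichment score alone (no permutation null).

    Same running-sum statistic as :func:`gsea_preranked`: genes ordered
    by decreasing statistic, hits weighted by |stat|^weight normalized
    to total 1, misses decremented by 1/(N - Nh).
    """
    order = ranked_stats.sort_values(ascending=False, kind="stable")
    genes = order.index.to_numpy()
    in_set = np.isin(genes, list(set(gene_set)))
    es, _ = _running_sum_es(genes, order.to_numpy(dtype=float), in_set, weight)
    return es


def gsea_preranked(
    ranked_stats: pd.Series,
    gene_set: set[str] | list[str],
    set_name: str = "gene_set",
    weight: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> EnrichmentScoreResult:
    """Preranked GSEA with a gene-set permutation null.

    Genes are ordered by decreasing statistic; hits increment the running
    sum by |stat|^weight (normalized to total 1), misses decrement it
    uniformly. ES is the signed maximum deviation. The null permutes
    set membership over the ranked universe; NES = ES / mean(|permuted
    ES| of the same sign); p = (1 + #{same-sign permutations at least as
    extreme}) / (n_perm + 1).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    gene_set = set(gene_set)
    universe = set(ranked_stats.index)
    if not gene_set:
        raise ValueError("empty gene set")
    if not gene_set <= universe:
        raise ValueError("gene set is not a subset of the ranked universe")
    if gene_set == universe:
        raise ValueError("gene set equals the ranked universe")

    order = ranked_stats.sort_values(ascending=False, kind="stable")
    genes = order.index.to_numpy()
    vals = order.to_numpy(dtype=float)
    in_set = np.isin(genes, list(gene_set))
    es, i_star = _running_sum_es(genes, vals, in_set, weight)

    rng = np.random.default_rng(seed)
    n, k = len(genes), len(gene_set)
    perm_es = np.empty(n_perm)
    for b in range(n_perm):
        idx = rng.choice(n, size=k, replace=False)
        mask = np.zeros(n, dtype=bool)
        mask[idx] = True
        perm_es[b], _ = _running_sum_es(genes, vals, mask, weight)

    same_sign = perm_es * np.sign(es) > 0 if es != 0 else np.ones(n_perm, bool)
    denom_vals = np.abs(perm_es[same_sign])
    nes = float(es / denom_vals.mean()) if denom_vals.size else float("nan")
    p = float((1 + int((denom_vals >= abs(es)).sum())) / (n_perm + 1))

    if es >= 0:
        leading = [g for g, h in zip(genes[: i_star + 1], in_set[: i_star + 1]) if h]
    else:
        leading = [g for g, h in zip(genes[i_star:], in_set[i_star:]) if h]
    return EnrichmentScoreResult(set_name, es, nes, p, leading)


@dataclass
class BinnedCorrelation:
    bin_means: pd.DataFrame  # columns: mean_fc, mean_binding
    r_bins: float  # Pearson r over bin means (nan if degenerate)
    r_genes: float
    degenerate: bool


def binned_binding_correlation(
    fc_per_gene: pd.Series,
    delta_binding_per_gene: pd.Series,
    bin_size: int = 10,
) -> BinnedCorrelation:
    """Bin-of-``bin_size`` summary of the binding-expression relation.

    Genes are sorted by decreasing fold change (ties broken by gene id
    for determinism) and cut into consecutive non-overlapping bins; a
    trailing partial bin is dropped. Pearson r is computed over the bin
    means; zero variance in either bin-mean vector is flagged degenerate.
    """
    common = fc_per_gene.index.intersection(delta_binding_per_gene.index)
    if not fc_per_gene.index.equals(delta_binding_per_gene.index):
        raise ValueError("fold-change and binding vectors are not aligned")
    n = len(common)
    if n < 2 * bin_size:
        raise ValueError("need at least two full bins of genes")
    df = pd.DataFrame({"fc": fc_per_gene, "binding": delta_binding_per_gene})
    df = df.iloc[np.lexsort((df.index.to_numpy(), -df["fc"].to_numpy()))]
    n_bins = n // bin_size
    df = df.iloc[: n_bins * bin_size]
    groups = np.repeat(np.arange(n_bins), bin_size)
    means = df.groupby(groups).mean()
    means.columns = ["mean_fc", "mean_binding"]

    degenerate = (
        np.ptp(means["mean_fc"].to_numpy()) == 0
        or np.ptp(means["mean_binding"].to_numpy()) == 0
    )
    if degenerate:
        r_bins = float("nan")
    else:
        r_bins = float(stats.pearsonr(means["mean_fc"], means["mean_binding"])[0])
    if np.ptp(df["fc"].to_numpy()) == 0 or np.ptp(df["binding"].to_numpy()) == 0:
        r_genes = float("nan")
    else:
        r_genes = float(stats.pearsonr(df["fc"], df["binding"])[0])
    return BinnedCorrelation(means, r_bins, r_genes, bool(degenerate))
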