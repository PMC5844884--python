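"""Signature scoring and metastasis-free survival stratification.

A gene-expression signature is summarized per sample as the mean of
gene-wise standardized (z-scored) expression values, re-centered so the
cohort scores have zero mean; samples with positive score are signature
High, negative score Low. High/Low groups are compared with the
Kaplan-Meier product-limit estimator and the log-rank (Mantel-Cox)
test. The product-limit estimate and the test statistic are computed by
lifelines.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

logger = logging.getLogger(__name__)


@dataclass
class SurvivalCohort:
    """Per-sample expression, follow-up and subtype of a patient cohort.

    ``expression``: genes x samples; ``meta``: indexed by sample with
    columns time (months, > 0), event (1 = metastasis, 0 = censored) and
    subtype.
    """

    expression: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if not set(self.expression.columns) == set(self.meta.index):
            raise ValueError("expression samples and metadata do not match")
        if (self.meta["time"] <= 0).any():
            raise ValueError("follow-up times must be positive")
        if not self.meta["event"].isin([0, 1]).all():
            raise ValueError("event flags must be 0 or 1")


def signature_score(
    expression: pd.DataFrame, signature: list[str] | set[str]
) -> pd.Series:
    """Zero-mean combined score of standardized signature-gene expression.

    Each measured signature gene is standardized across samples (mean 0,
    sd 1); a sample's score is the mean over signature genes, re-centered
    so the cohort mean is exactly zero. Missing and zero-variance genes
    are dropped with a log entry.
    """
    if expression.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    sig = sorted(set(signature))
    present = [g for g in sig if g in expression.index]
    for g in set(sig) - set(present):
        logger.info("signature gene %s not measured; dropped", g)
    if not present:
        raise ValueError("no signature gene measured")
    sub = expression.loc[present].astype(float)
    sd = sub.std(axis=1, ddof=0)
    zero_var = sd == 0
    for g in sub.index[zero_var]:
        logger.info("signature gene %s has zero variance; dropped", g)
    sub = sub.loc[~zero_var]
    if sub.empty:
        raise ValueError("all signature genes have zero variance")
    z = sub.sub(sub.mean(axis=1), axis=0).div(sd[~zero_var], axis=0)
    scores = z.mean(axis=0)
    return scores - scores.mean()


def classify(scores: pd.Series) -> pd.Series:
    """High iff score > 0, Low otherwise (exact zeros are Low, warned)."""
    if (scores == 0).any():
        warnings.warn("scores exactly 0 classified as Low", stacklevel=2)
    return pd.Series(
        np.where(scores.to_numpy() > 0, "High", "Low"), index=scores.index
    )


def subgroup_average(
    expression: pd.DataFrame,
    signature: list[str] | set[str],
    groups: pd.Series,
) -> pd.Series:
    """Standardized average signature expression per sample subgroup.

    Genes are standardized across ALL samples, then averaged over
    signature genes and samples within each subgroup; the values are
    adimensional. Empty subgroups are omitted with a log entry.
    """
    missing = [s for s in expression.columns if s not in groups.index]
    if missing:
        raise ValueError(f"samples without group label: {missing}")
    present = [g for g in sorted(set(signature)) if g in expression.index]
    if not present:
        raise ValueError("no signature gene measured")
    sub = expression.loc[present].astype(float)
    sd = sub.std(axis=1, ddof=0)
    sub = sub.loc[sd > 0]
    z = sub.sub(sub.mean(axis=1), axis=0).div(sd[sd > 0], axis=0)
    out = {}
    for group in pd.unique(groups.loc[list(expression.columns)]):
        cols = [s for s in expression.columns if groups[s] == group]
        if not cols:
            logger.info("subgroup %s empty; omitted", group)
            continue
        out[group] = float(z[cols].to_numpy().mean())
    return pd.Series(out, name="standardized_average")


def km_estimate(times, events) -> pd.DataFrame:
    """Kaplan-Meier product-limit estimate of event-free probability.

    Returns a step function table (columns: time, survival); the curve
    starts at 1, is right-continuous and non-increasing; censored times
    do not drop the curve.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if len(times) == 0:
        raise ValueError("need at least one observation")
    if (times <= 0).any():
        raise ValueError("times must be positive")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    sf = kmf.survival_function_
    return pd.DataFrame(
        {"time": sf.index.to_numpy(dtype=float), "survival": sf.iloc[:, 0].to_numpy()}
    )


def logrank(
    times_a, events_a, times_b, events_b
) -> dict:
    """Mantel-Cox log-rank comparison of two survival curves.

    Returns the 1-df chi-square statistic and its two-sided p-value.
    """
    ta, tb = np.asarray(times_a, float), np.asarray(times_b, float)
    ea, eb = np.asarray(events_a, int), np.asarray(events_b, int)
    if len(ta) == 0 or len(tb) == 0:
        raise ValueError("both groups must be non-empty")
    if ea.sum() + eb.sum() == 0:
        raise ValueError("log-rank needs at least one event")
    res = logrank_test(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return {"statistic": float(res.test_statistic), "p_value": float(res.p_value)}
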