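"""Spearman correlation analyses with BH adjustment.

Covers the three correlation layers of the pipeline: arbitrary paired
vectors (pathway expression vs metabolite abundance), per-pathway mean
expression vs a per-sample feature such as growth rate, and the
OXPHOS-vs-EMT comparison in survival-stratified patients, where each
sample is summarized by its median expression over the two gene sets.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust
from .signature import MetabolicSignature
from .survival import SurvivalGroups

logger = logging.getLogger(__name__)

__all__ = ["spearman_bh", "pathway_vs_feature", "oxphos_vs_emt"]


def spearman_bh(pairs: Sequence[tuple]) -> pd.DataFrame:
    """Spearman rho (average ranks) and p for each (x, y, label) triple, with
    BH adjustment across all pairs in the call.

    Incomplete observations are dropped pairwise; a pair with a constant
    vector gets NaN and is excluded from BH; fewer than 3 complete
    observations is an error.
    """
    recs = []
    for x, y, label in pairs:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        n = int(ok.sum())
        if n < 3:
            raise ValueError(f"pair {label!r}: fewer than 3 complete observations")
        xv, yv = x[ok], y[ok]
        if np.ptp(xv) == 0 or np.ptp(yv) == 0:
            rho, p = np.nan, np.nan
        else:
            rho, p = stats.spearmanr(xv, yv)
        recs.append({"label": label, "rho": rho, "pvalue": p, "n": n})
    out = pd.DataFrame(recs).set_index("label")
    out["qvalue"] = bh_adjust(out["pvalue"].values)
    return out


def _pathway_means(expr: pd.DataFrame, sig: MetabolicSignature) -> pd.DataFrame:
    """Per-sample mean expression of each pathway's measured genes
    (pathways x samples)."""
    rows = {}
    for name, genes in sig.pathways.items():
        present = [g for g in genes if g in expr.index]
        if not present:
            logger.info("pathway %r has no measured genes; dropped", name)
            continue
        rows[name] = expr.loc[present].mean(axis=0)
    return pd.DataFrame(rows).T


def pathway_vs_feature(
    expr: pd.DataFrame, sig: MetabolicSignature, feature: pd.Series
) -> pd.DataFrame:
    """Correlate each pathway's per-sample mean expression with a per-sample
    feature (e.g. growth rate), BH across pathways."""
    if hasattr(expr, "provenance"):  # accept a VSTMatrix as-is
        expr = expr.values
    feature = pd.Series(feature)
    missing = expr.columns.difference(feature.index)
    if len(missing):
        raise ValueError(f"feature missing for samples: {list(missing)[:5]}")
    pm = _pathway_means(expr, sig)
    f = feature.loc[expr.columns].values
    pairs = [(pm.loc[name].values, f, name) for name in pm.index]
    return spearman_bh(pairs)


def oxphos_vs_emt(
    expr_by_cohort: Mapping[str, pd.DataFrame],
    oxphos_set,
    emt_set,
    groups_by_cohort: Mapping[str, SurvivalGroups],
) -> pd.DataFrame:
    """Correlation between OXPHOS and EMT expression in survival-stratified
    patients, one coefficient per cohort.

    Within each cohort, samples are restricted to the union of the high- and
    low-survival groups; each sample contributes one point: (median
    expression over OXPHOS genes, median expression over EMT genes).
    Spearman rho is computed across those per-sample medians and BH applied
    across cohorts.  The high/low labels themselves do not enter the
    correlation, so swapping them changes nothing.
    """
    oxphos_set, emt_set = set(oxphos_set), set(emt_set)
    if not oxphos_set or not emt_set:
        raise ValueError("OXPHOS and EMT gene sets must be non-empty")
    pairs = []
    for cohort, expr in expr_by_cohort.items():
        g = groups_by_cohort[cohort]
        samples = [s for s in expr.columns if s in (g.high | g.low)]
        ox = [x for x in oxphos_set if x in expr.index]
        em = [x for x in emt_set if x in expr.index]
        if not ox or not em:
            raise ValueError(f"cohort {cohort}: gene sets unmeasured")
        ox_med = expr.loc[ox, samples].median(axis=0).values
        em_med = expr.loc[em, samples].median(axis=0).values
        pairs.append((ox_med, em_med, cohort))
    return spearman_bh(pairs)
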