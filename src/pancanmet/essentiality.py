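"""shRNA-screen essentiality analysis.

Gene-level essentiality scores (ATARIS convention: lower = more essential)
across cancer cell lines are analysed three ways: a per-gene one-way ANOVA
of score against tissue of origin (BH-adjusted) flags genes whose
essentiality is tissue-predicted; the top 5% most essential genes of each
cell line, unioned over the cell lines of a tissue, give a per-tissue
essential-gene list; and the number of tissues in which each gene is
essential ("occurrence"), averaged over the genes of a pathway, measures
tissue-independent pathway essentiality.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust
from .signature import MetabolicSignature

logger = logging.getLogger(__name__)

__all__ = [
    "EssentialityMatrix",
    "anova_by_tissue",
    "top_essential",
    "tissue_occurrence",
]


@dataclass
class EssentialityMatrix:
    """Gene x cell-line score matrix plus the cell-line -> tissue map."""

    scores: pd.DataFrame
    tissue_map: pd.Series  # index: cell line, value: tissue

    def __post_init__(self):
        if not isinstance(self.tissue_map, pd.Series):
            self.tissue_map = pd.Series(dict(self.tissue_map))
        missing = self.scores.columns.difference(self.tissue_map.index)
        if len(missing):
            raise ValueError(f"cell lines without tissue: {list(missing)[:5]}")


def anova_by_tissue(e: EssentialityMatrix, q_threshold: float = 0.05) -> pd.DataFrame:
    """One-way ANOVA of essentiality score against tissue, per gene.

    Vectorized across genes: F = between-tissue mean square / within-tissue
    mean square, with NA scores ignored.  Genes observed in fewer than two
    tissues (or without residual degrees of freedom) get NaN and are left
    out of the BH adjustment.  ``tissue_predicted`` flags BH q < 0.05.
    """
    all_tissues = sorted(e.tissue_map.unique())
    counts_per_tissue = e.tissue_map.value_counts()
    if (counts_per_tissue >= 2).sum() < 2:
        raise ValueError("need >=2 tissues with >=2 cell lines each")

    X = e.scores.values.astype(float)
    ok = np.isfinite(X)
    G = X.shape[0]

    grand_sum = np.where(ok, X, 0.0).sum(axis=1)
    n_total = ok.sum(axis=1)

    ss_between = np.zeros(G)
    k_used = np.zeros(G, dtype=int)
    for t in all_tissues:
        cols = (e.tissue_map.loc[e.scores.columns] == t).values
        okt = ok[:, cols]
        nt = okt.sum(axis=1)
        st = np.where(okt, X[:, cols], 0.0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            ss_between += np.where(nt > 0, st**2 / np.maximum(nt, 1), 0.0)
        k_used += (nt > 0).astype(int)
    with np.errstate(invalid="ignore", divide="ignore"):
        ss_between -= grand_sum**2 / np.maximum(n_total, 1)
        ss_total = np.where(ok, X, 0.0).__pow__(2).sum(axis=1) - grand_sum**2 / np.maximum(n_total, 1)
    ss_within = ss_total - ss_between

    df_b = k_used - 1
    df_w = n_total - k_used
    valid = (df_b >= 1) & (df_w >= 1) & (ss_within > 0)
    F = np.full(G, np.nan)
    p = np.full(G, np.nan)
    F[valid] = (ss_between[valid] / df_b[valid]) / (ss_within[valid] / df_w[valid])
    p[valid] = stats.f.sf(F[valid], df_b[valid], df_w[valid])

    out = pd.DataFrame({"F": F, "pvalue": p}, index=e.scores.index)
    out["qvalue"] = bh_adjust(p)
    out["tissue_predicted"] = out["qvalue"] < q_threshold
    n_excl = int((~valid).sum())
    if n_excl:
        logger.info("anova_by_tissue: %d genes not testable (excluded from BH)", n_excl)
    return out


def top_essential(
    e: EssentialityMatrix, fraction: float = 0.05, higher_is_essential: bool = False
) -> Dict[str, frozenset]:
    """Per cell line, the floor(fraction * n_scored) genes with the most
    essential (lowest, by default) scores.

    Only genes with non-NA scores in that cell line count toward n_scored;
    boundary ties are broken by gene identifier so the call is deterministic.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    out = {}
    sign = -1.0 if higher_is_essential else 1.0
    for cl in e.scores.columns:
        s = e.scores[cl].dropna()
        n_take = int(np.floor(fraction * len(s)))
        order = sorted(s.index, key=lambda g: (sign * s[g], g))
        out[cl] = frozenset(order[:n_take])
    return out


def tissue_occurrence(
    sets: Mapping[str, frozenset],
    tissue_map: pd.Series,
    sig: MetabolicSignature,
    scored_genes=None,
) -> dict:
    """Aggregate per-cell-line essential-gene sets into tissue occurrence.

    A tissue's essential set is the union over its cell lines; a gene's
    occurrence is the number of tissues whose set contains it; a pathway's
    value is the mean occurrence over its genes present among the scored
    genes.  Pathways with no scored genes are dropped with a log entry.
    """
    if not isinstance(tissue_map, pd.Series):
        tissue_map = pd.Series(dict(tissue_map))
    tissue_sets: Dict[str, set] = {}
    for cl, genes in sets.items():
        tissue_sets.setdefault(tissue_map[cl], set()).update(genes)

    if scored_genes is None:
        scored_genes = set().union(*sets.values()) if sets else set()
        # default universe: every gene that appears in any per-line set is
        # certainly scored; callers should pass the full scored universe
        # when they have it
    scored_genes = set(scored_genes)

    occurrence = pd.Series(
        {g: sum(g in ts for ts in tissue_sets.values()) for g in scored_genes},
        dtype=int,
    ).sort_index()

    pw = {}
    for name, genes in sig.pathways.items():
        present = [g for g in genes if g in scored_genes]
        if not present:
            logger.info("tissue_occurrence: pathway %r has no scored genes; dropped",
                        name)
            continue
        pw[name] = occurrence.loc[present].mean()
    return {
        "gene_occurrence": occurrence,
        "pathway_occurrence": pd.Series(pw).sort_index(),
        "tissue_sets": {t: frozenset(s) for t, s in tissue_sets.items()},
    }
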