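"""Directional permutation gene-set enrichment analysis (GSEA).

Given a vector of signed gene-level statistics (Wald or t statistics,
optionally promiscuity-corrected), genes are ranked by decreasing statistic
and each pathway is scored with the weighted Kolmogorov-Smirnov-like running
sum of Subramanian et al.: walking down the ranking, hitting a set member
increments the sum by |s|^w normalized over the set, missing decrements by
1/(N - N_h); the enrichment score (ES) is the signed maximal deviation from
zero.  Significance is assessed against a gene-label permutation null shared
across pathways, with separate p-values for the up (ES > 0) and down
(ES < 0) directions and BH adjustment within each direction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._stats import bh_adjust
from .signature import MetabolicSignature, compute_promiscuity, correct_statistic

logger = logging.getLogger(__name__)

__all__ = [
    "RankedList",
    "rank_genes",
    "running_es",
    "permutation_pvalues",
    "gsea_pipeline",
]

DEFAULT_MIN_SET_SIZE = 5
DEFAULT_MAX_SET_SIZE = 500
DEFAULT_N_PERM = 1000


@dataclass(frozen=True)
class RankedList:
    """Genes ordered by decreasing statistic, ties broken by identifier."""

    genes: tuple
    stats: np.ndarray  # aligned with genes, decreasing

    def __post_init__(self):
        if len(self.genes) != len(self.stats):
            raise ValueError("genes and stats differ in length")

    def __len__(self):
        return len(self.genes)


def rank_genes(stats: Mapping[str, float]) -> RankedList:
    """Sort genes by decreasing statistic; ties broken lexicographically by
    gene identifier so the ordering is deterministic."""
    s = pd.Series(dict(stats)) if not isinstance(stats, pd.Series) else stats
    s = s.dropna()
    order = sorted(s.index, key=lambda g: (-s[g], g))
    return RankedList(tuple(order), s.loc[order].to_numpy(dtype=float))


def _es_from_mask(weights: np.ndarray, hit: np.ndarray) -> float:
    """ES for one hit mask over the ranked weight vector |s|^w."""
    n = weights.shape[0]
    nh = int(hit.sum())
    if nh == 0 or nh == n:
        raise ValueError("gene set must be a strict non-empty subset of the universe")
    wh = weights * hit
    denom = wh.sum()
    if denom == 0:  # all hit statistics are exactly zero: uniform increments
        inc = hit / nh
    else:
        inc = wh / denom
    run = np.cumsum(inc - (1.0 - hit) / (n - nh))
    i = int(np.argmax(np.abs(run)))
    return float(run[i])


def _es_batch(weights: np.ndarray, hits: np.ndarray) -> np.ndarray:
    """ES for a (B, N) batch of hit masks (all with the same set size)."""
    B, n = hits.shape
    nh = hits[0].sum()
    wh = weights[None, :] * hits
    denom = wh.sum(axis=1, keepdims=True)
    inc = np.where(denom > 0, wh / np.where(denom == 0, 1.0, denom), hits / nh)
    run = np.cumsum(inc - (1.0 - hits) / (n - nh), axis=1)
    idx = np.argmax(np.abs(run), axis=1)
    return run[np.arange(B), idx]


def running_es(ranked: RankedList, geneset, weight: float = 1.0,
               min_set_size: int = DEFAULT_MIN_SET_SIZE) -> float:
    """Enrichment score of one gene set against a ranked list.

    The set is intersected with the ranked universe; an intersection smaller
    than ``min_set_size`` (or equal to the whole universe) is rejected.
    """
    members = set(geneset)
    hit = np.fromiter((g in members for g in ranked.genes), dtype=float,
                      count=len(ranked))
    if hit.sum() < min_set_size:
        raise ValueError(
            f"gene set overlaps the universe in {int(hit.sum())} genes "
            f"(< min_set_size={min_set_size})"
        )
    weights = np.abs(ranked.stats) ** weight
    return _es_from_mask(weights, hit)


def permutation_pvalues(
    ranked: RankedList,
    sig: MetabolicSignature,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    weight: float = 1.0,
    min_set_size: int = DEFAULT_MIN_SET_SIZE,
    max_set_size: int = DEFAULT_MAX_SET_SIZE,
) -> pd.DataFrame:
    """Directional permutation p-values for every pathway in the signature.

    The null redistributes gene labels: each of the ``n_perm`` permutations
    reshuffles which ranked positions belong to a pathway, and the same
    permutations are shared by all pathways.  For each pathway
    ``p_up = (1 + #{null ES >= observed}) / (n_perm + 1)`` and
    ``p_down = (1 + #{null ES <= observed}) / (n_perm + 1)``; BH adjustment is
    applied across pathways within each direction.  The plus-one estimator
    keeps every p-value strictly positive; a fixed seed makes the result
    deterministic.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100 for a usable permutation tail")
    n = len(ranked)
    universe = set(ranked.genes)
    weights = np.abs(ranked.stats) ** weight
    pos = {g: i for i, g in enumerate(ranked.genes)}
    # canonical gene ordering, independent of the ranking, so that the
    # seed-derived label permutations are shared across pathways and the
    # null is equivariant under a global sign flip of the statistics
    genes_sorted = sorted(universe)
    rankpos = np.array([pos[g] for g in genes_sorted])
    sorted_idx = {g: j for j, g in enumerate(genes_sorted)}

    rows = []
    set_idx = {}
    for name, genes in sig.pathways.items():
        inset = [g for g in genes if g in universe]
        size = len(inset)
        if size < min_set_size or size > min(max_set_size, n - 1):
            logger.info("pathway %r skipped (usable size %d)", name, size)
            continue
        mask = np.zeros(n)
        mask[[pos[g] for g in inset]] = 1.0
        set_idx[name] = np.array([sorted_idx[g] for g in inset])
        rows.append((name, size, _es_from_mask(weights, mask)))
    if not rows:
        return pd.DataFrame(
            columns=["size", "ES", "p_up", "p_down", "q_up", "q_down", "direction"]
        )

    rng = np.random.default_rng(seed)
    perms = np.stack([rng.permutation(n) for _ in range(n_perm)])  # shared

    p_up, p_down = [], []
    for name, size, es in rows:
        cols = rankpos[perms[:, set_idx[name]]]  # (B, size) null hit positions
        hits = np.zeros((n_perm, n))
        hits[np.repeat(np.arange(n_perm), size), cols.ravel()] = 1.0
        null = _es_batch(weights, hits)
        p_up.append((1.0 + np.sum(null >= es)) / (n_perm + 1.0))
        p_down.append((1.0 + np.sum(null <= es)) / (n_perm + 1.0))

    out = pd.DataFrame(
        {
            "size": [r[1] for r in rows],
            "ES": [r[2] for r in rows],
            "p_up": p_up,
            "p_down": p_down,
        },
        index=[r[0] for r in rows],
    )
    out["q_up"] = bh_adjust(out["p_up"].values)
    out["q_down"] = bh_adjust(out["p_down"].values)
    out["direction"] = np.where(out["ES"] > 0, "up", np.where(out["ES"] < 0, "down", "none"))
    return out


def gsea_pipeline(
    de: pd.DataFrame,
    sig: MetabolicSignature,
    prom_correct: bool = True,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    weight: float = 1.0,
    q_threshold: float = 0.05,
    stat_column: str = "stat",
    min_set_size: int = DEFAULT_MIN_SET_SIZE,
    max_set_size: int = DEFAULT_MAX_SET_SIZE,
) -> pd.DataFrame:
    """Full enrichment pipeline on a differential-expression result.

    Takes the signed gene-level statistic column, optionally applies the
    promiscuity correction, restricts to signature genes, ranks, and runs the
    permutation test.  Adds a ``significant`` column: ``upregulated`` /
    ``downregulated`` by sign of ES at q < ``q_threshold`` in the matching
    direction, else ``ns``.
    """
    stats_in = de[stat_column].dropna()
    if prom_correct:
        prom = compute_promiscuity(sig)
        stats_in = correct_statistic(stats_in, prom)
    else:
        in_sig = stats_in.index.intersection(pd.Index(sorted(sig.genes)))
        n_dropped = len(stats_in) - len(in_sig)
        if n_dropped:
            logger.info("gsea_pipeline: dropped %d genes absent from signature", n_dropped)
        stats_in = stats_in.loc[in_sig]
    ranked = rank_genes(stats_in)
    res = permutation_pvalues(
        ranked, sig, n_perm=n_perm, seed=seed, weight=weight,
        min_set_size=min_set_size, max_set_size=max_set_size,
    )
    if res.empty:
        res["significant"] = pd.Series(dtype=object)
        return res
    sig_call = np.where(
        (res["ES"] > 0) & (res["q_up"] < q_threshold), "upregulated",
        np.where((res["ES"] < 0) & (res["q_down"] < q_threshold), "downregulated", "ns"),
    )
    res["significant"] = sig_call
    return res
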