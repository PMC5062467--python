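"""Tissue-independent clustering of cancer samples on pathway-mean
expression.

All cancer samples are represented by the mean variance-stabilized
expression of each metabolic pathway's genes, clustered with PAM
(partitioning around medoids, BUILD + SWAP) on Euclidean distances, the
number of clusters chosen by the Tibshirani gap statistic with a uniform
reference and the 1-SE rule, and each cluster tested for over-representation
of tissues of origin with an upper-tail hypergeometric test (BH-adjusted).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist

from ._stats import bh_adjust
from .rewiring import VSTMatrix
from .signature import MetabolicSignature

logger = logging.getLogger(__name__)

__all__ = [
    "pathway_score_matrix",
    "pam",
    "gap_statistic",
    "tissue_enrichment",
    "PAMResult",
    "GapResult",
]


def pathway_score_matrix(v: VSTMatrix, sig: MetabolicSignature) -> pd.DataFrame:
    """Samples x pathways matrix of mean VST expression over each pathway's
    measured genes; pathways with no measured gene are dropped (logged)."""
    cols = {}
    for name, genes in sig.pathways.items():
        present = [g for g in genes if g in v.values.index]
        if not present:
            logger.info("pathway_score_matrix: pathway %r unmeasured; dropped", name)
            continue
        cols[name] = v.values.loc[present].mean(axis=0)
    return pd.DataFrame(cols)


@dataclass
class PAMResult:
    medoids: np.ndarray      # indices into the sample axis, sorted
    assignment: np.ndarray   # per-sample medoid position (0..k-1)
    cost: float              # total distance of samples to their medoid


def _assign(D: np.ndarray, medoids: np.ndarray):
    sub = D[:, medoids]
    a = np.argmin(sub, axis=1)
    return a, float(sub[np.arange(D.shape[0]), a].sum())


def _build(D: np.ndarray, k: int) -> list:
    """Greedy BUILD initialization; distance ties broken by lowest index."""
    n = D.shape[0]
    medoids = [int(np.argmin(D.sum(axis=1)))]
    while len(medoids) < k:
        dnear = D[:, medoids].min(axis=1)
        # gain of adding candidate c: sum over points of max(dnear - d(c, .), 0)
        gain = np.maximum(dnear[None, :] - D, 0.0).sum(axis=1)
        gain[medoids] = -np.inf
        medoids.append(int(np.argmax(gain)))
    return medoids


def _swap(D: np.ndarray, medoids: list, max_iter: int = 200) -> PAMResult:
    """SWAP phase: repeatedly apply the single best (medoid, non-medoid)
    exchange while it strictly lowers total cost.

    For a fixed medoid m to remove, the post-swap cost with candidate h is
    sum_i min(d(i, h), alt_i), where alt_i is the distance to the nearest
    surviving medoid (second-nearest overall when i was assigned to m);
    this evaluates all candidates for one medoid in a single vector op.
    Ties are broken by lowest candidate index (argmin convention).
    """
    n = D.shape[0]
    medoids = list(medoids)
    k = len(medoids)
    _, cost = _assign(D, np.array(medoids))
    for _ in range(max_iter):
        med = np.array(medoids)
        sub = D[:, med]
        order = np.argsort(sub, axis=1, kind="stable")
        dnear = sub[np.arange(n), order[:, 0]]
        nearest = med[order[:, 0]]
        dsecond = sub[np.arange(n), order[:, 1]] if k > 1 else np.full(n, np.inf)
        best_delta, best_mi, best_h = 0.0, None, None
        for mi, m in enumerate(medoids):
            alt = np.where(nearest == m, dsecond, dnear)
            swap_costs = np.minimum(D, alt[:, None]).sum(axis=0)
            swap_costs[med] = np.inf
            h = int(np.argmin(swap_costs))
            delta = swap_costs[h] - cost
            if delta < best_delta - 1e-12:
                best_delta, best_mi, best_h = delta, mi, h
        if best_mi is None:
            break
        medoids[best_mi] = best_h
        _, cost = _assign(D, np.array(medoids))
    med = np.array(sorted(medoids))
    a, cost = _assign(D, med)
    return PAMResult(medoids=med, assignment=a, cost=cost)


def pam(x, k: int, init: Optional[list] = None) -> PAMResult:
    """k-medoids via BUILD + SWAP on Euclidean distances.

    Deterministic: BUILD is greedy and ties are broken by lowest sample
    index, so no randomness is involved.  The returned configuration is
    locally optimal: no single medoid/non-medoid exchange lowers the cost.
    """
    X = np.asarray(x.values if isinstance(x, pd.DataFrame) else x, dtype=float)
    n = X.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range 1..{n}")
    D = cdist(X, X)
    if k == n:
        return PAMResult(medoids=np.arange(n), assignment=np.arange(n), cost=0.0)
    medoids = init if init is not None else _build(D, k)
    return _swap(D, medoids)


@dataclass
class GapResult:
    k: int
    curve: pd.DataFrame  # columns k, gap, se, log_w, mean_log_w_ref


def gap_statistic(x, k_max: int, B: int = 50, seed: int = 0) -> GapResult:
    """Tibshirani gap statistic for choosing the number of PAM clusters.

    Reference datasets are uniform over each feature's observed range
    (zero-range features are dropped from reference generation, logged);
    Gap(k) = mean_B log W*_k - log W_k with W_k the PAM cost, and the chosen
    k is the smallest with Gap(k) >= Gap(k+1) - s_{k+1}, where
    s_k = sd_k * sqrt(1 + 1/B).

    Within one call the PAM cost is kept non-increasing in k by also warm-
    starting each k from the previous solution plus its best extra medoid
    and keeping the cheaper configuration.
    """
    X = np.asarray(x.values if isinstance(x, pd.DataFrame) else x, dtype=float)
    n = X.shape[0]
    if not (1 <= k_max < n):
        raise ValueError("need 1 <= k_max < n_samples")
    if B < 10:
        raise ValueError("B must be >= 10")
    rng = np.random.default_rng(seed)

    lo, hi = X.min(axis=0), X.max(axis=0)
    span = hi - lo
    keep = span > 0
    if (~keep).any():
        logger.info("gap_statistic: dropping %d zero-range features from reference",
                    int((~keep).sum()))

    def cost_curve(M: np.ndarray) -> np.ndarray:
        out = np.empty(k_max)
        prev = None
        for k in range(1, k_max + 1):
            res = pam(M, k)
            if prev is not None:
                warm = _extend_medoids(M, prev.medoids)
                res2 = _swap(cdist(M, M), warm)
                if res2.cost < res.cost:
                    res = res2
            out[k - 1] = res.cost
            prev = res
        return out

    W = cost_curve(X)
    logW = np.log(np.maximum(W, 1e-300))

    logWref = np.empty((B, k_max))
    for b in range(B):
        R = np.empty_like(X)
        R[:, keep] = rng.uniform(lo[keep], hi[keep], size=(n, int(keep.sum())))
        R[:, ~keep] = X[:, ~keep]
        logWref[b] = np.log(np.maximum(cost_curve(R), 1e-300))

    gap = logWref.mean(axis=0) - logW
    sd = logWref.std(axis=0, ddof=0)
    se = sd * np.sqrt(1.0 + 1.0 / B)

    chosen = k_max
    for k in range(1, k_max):
        if gap[k - 1] >= gap[k] - se[k]:
            chosen = k
            break
    curve = pd.DataFrame(
        {"k": np.arange(1, k_max + 1), "gap": gap, "se": se,
         "log_w": logW, "mean_log_w_ref": logWref.mean(axis=0)}
    )
    return GapResult(k=chosen, curve=curve)


def _extend_medoids(M: np.ndarray, medoids: np.ndarray) -> list:
    """Previous medoid set plus the single best additional medoid."""
    D = cdist(M, M)
    dnear = D[:, medoids].min(axis=1)
    gain = np.maximum(dnear[None, :] - D, 0.0).sum(axis=1)
    gain[medoids] = -np.inf
    return list(medoids) + [int(np.argmax(gain))]


def tissue_enrichment(assignment, labels, q_threshold: float = 0.05) -> pd.DataFrame:
    """Hypergeometric over-representation of cancer types within clusters.

    For each (cluster, type): upper-tail probability of observing at least
    the seen number of type members in the cluster, drawing cluster-size
    samples without replacement from the population.  BH across all pairs;
    ``enriched`` flags q < ``q_threshold``.  Also reports the proportion of
    each type's samples falling in the cluster.
    """
    a = pd.Series(assignment)
    l = pd.Series(labels)
    if len(a) != len(l):
        raise ValueError("assignment and labels differ in length")
    M = len(a)
    recs = []
    for cl in sorted(a.unique()):
        in_cl = a == cl
        N = int(in_cl.sum())
        for t in sorted(l.unique()):
            n_type = int((l == t).sum())
            x = int((in_cl & (l == t)).sum())
            p = stats.hypergeom.sf(x - 1, M, n_type, N)
            recs.append({"cluster": cl, "cancer_type": t, "count": x,
                         "cluster_size": N, "type_total": n_type,
                         "pvalue": float(p),
                         "type_proportion": x / n_type if n_type else np.nan})
    out = pd.DataFrame(recs)
    out["qvalue"] = bh_adjust(out["pvalue"].values)
    out["enriched"] = out["qvalue"] < q_threshold
    return out
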