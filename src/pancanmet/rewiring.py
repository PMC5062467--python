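"""Tissue-specific metabolic rewiring scores.

Pooled normal samples and pooled cancer samples are each variance-stabilized
independently; per gene, the tissue mean expression x̄_{i,t} is divided by
the unweighted average of the tissue means across tissues, giving a fold
change r_{i,t} of every gene in every tissue relative to the "average
tissue".  Averaging r over the genes of a pathway yields the pathway score
S_{p,t}; the matrices of scores for normal tissues (N_p) and cancer tissues
(C_p) support (i) Spearman correlation of metabolic competence between each
normal tissue and its matched cancer, (ii) the cross-pathway standard
deviation per tissue as a measure of metabolic diversity, and (iii) a
classification of pathways as maintained / lost / gained in cancer relative
to the tissue of origin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust
from .diffexp import CountMatrix, size_factors, fit_dispersion_trend
from .signature import MetabolicSignature

logger = logging.getLogger(__name__)

__all__ = [
    "VSTMatrix",
    "vst",
    "tissue_means",
    "fold_vs_average",
    "pathway_scores",
    "normal_cancer_correlation",
    "diversity",
    "classify_rewiring",
]


@dataclass
class VSTMatrix:
    """Variance-stabilized expression (genes x samples) with provenance."""

    values: pd.DataFrame
    provenance: str  # "vst" or "shifted-log" (fallback)


def _fit_trend_for_vst(q: np.ndarray) -> tuple:
    """Fit alpha(mu) = a0 + a1/mu from moment dispersion estimates on
    normalized counts, pooled across all samples."""
    m = q.mean(axis=1)
    v = q.var(axis=1, ddof=1)
    disp = (v - m) / np.maximum(m, 1e-8) ** 2
    return fit_dispersion_trend(m, np.clip(disp, 1e-8, 30.0))


def vst(counts: CountMatrix, sf: pd.Series = None,
        pseudo_reference: bool = False) -> VSTMatrix:
    """Closed-form variance-stabilizing transformation.

    With the parametric trend alpha(mu) = a0 + a1/mu the NB variance is
    v(mu) = (1 + a1) mu + a0 mu^2, and the integral transform
    u(q) = ∫ dq/sqrt(v(q)) has the closed form
    (2/sqrt(a0)) * asinh(sqrt(a0 q / (1 + a1))) applied to size-factor
    normalized counts q.  Monotone increasing per gene; when the trend fit
    fails the fallback is log2(q + 1), tagged "shifted-log".
    """
    if sf is None:
        sf = size_factors(counts, pseudo_reference=pseudo_reference)
    q = counts.counts.values / sf.loc[counts.counts.columns].values[None, :]
    try:
        a0, a1 = _fit_trend_for_vst(q)
        u = (2.0 / np.sqrt(a0)) * np.arcsinh(np.sqrt(a0 * q / (1.0 + a1)))
        return VSTMatrix(
            pd.DataFrame(u, index=counts.counts.index, columns=counts.counts.columns),
            provenance="vst",
        )
    except RuntimeError:
        logger.warning(
            "VST: dispersion trend fit failed; FALLING BACK to log2(normalized+1)"
        )
        u = np.log2(q + 1.0)
        return VSTMatrix(
            pd.DataFrame(u, index=counts.counts.index, columns=counts.counts.columns),
            provenance="shifted-log",
        )


def tissue_means(v: VSTMatrix, grouping: Mapping[str, str]) -> pd.DataFrame:
    """Mean VST expression per gene per tissue (x̄_{i,t})."""
    g = pd.Series(dict(grouping))
    missing = v.values.columns.difference(g.index)
    if len(missing):
        raise ValueError(f"samples without tissue label: {list(missing)[:5]}")
    return v.values.T.groupby(g.loc[v.values.columns]).mean().T


def fold_vs_average(m: pd.DataFrame) -> pd.DataFrame:
    """Fold change of each gene in each tissue vs the average tissue.

    r_{i,t} = x̄_{i,t} / mean_t(x̄_{i,t}); the denominator is the unweighted
    mean over tissues.  Genes whose cross-tissue average is zero are set to
    NaN (and excluded downstream) with a logged count.
    """
    avg = m.mean(axis=1)
    zero = avg == 0
    if zero.any():
        logger.info("fold_vs_average: %d genes with zero cross-tissue average -> NaN",
                    int(zero.sum()))
    r = m.div(avg.where(~zero), axis=0)
    return r


def pathway_scores(r: pd.DataFrame, sig: MetabolicSignature) -> pd.DataFrame:
    """Pathway x tissue score matrix: S_{p,t} = mean over pathway genes of
    r_{i,t}.  Pathways with no measurable gene are dropped with a log entry."""
    rows = {}
    measurable = r.dropna(how="any")
    for name, genes in sig.pathways.items():
        present = [g for g in genes if g in measurable.index]
        if not present:
            logger.info("pathway_scores: pathway %r has no measurable genes; dropped",
                        name)
            continue
        rows[name] = measurable.loc[present].mean(axis=0)
    return pd.DataFrame(rows).T


def normal_cancer_correlation(
    N: pd.DataFrame, C: pd.DataFrame, pairing: Mapping[str, str],
    min_shared: int = 5,
) -> pd.DataFrame:
    """Spearman correlation of pathway scores between each normal tissue and
    its matched cancer type, BH-adjusted across pairs.

    ``pairing`` maps normal-tissue column of N to cancer column of C.  Pairs
    sharing fewer than ``min_shared`` pathways are skipped.
    """
    recs = []
    for normal_t, cancer_t in pairing.items():
        if normal_t not in N.columns or cancer_t not in C.columns:
            raise ValueError(f"unmatched tissue pairing {normal_t!r} -> {cancer_t!r}")
        shared = N.index.intersection(C.index)
        x = N.loc[shared, normal_t]
        y = C.loc[shared, cancer_t]
        ok = x.notna() & y.notna()
        if ok.sum() < min_shared:
            logger.info("pair %s/%s skipped: %d shared pathways", normal_t, cancer_t,
                        int(ok.sum()))
            continue
        rho, p = stats.spearmanr(x[ok], y[ok])
        recs.append({"normal": normal_t, "cancer": cancer_t,
                     "rho": rho, "pvalue": p, "n_pathways": int(ok.sum())})
    out = pd.DataFrame(recs)
    if not out.empty:
        out["qvalue"] = bh_adjust(out["pvalue"].values)
    return out


def diversity(scores: pd.DataFrame) -> pd.Series:
    """Cross-pathway metabolic diversity per tissue: sample standard
    deviation (n-1 denominator) of S_{p,t} over pathways."""
    if scores.shape[0] < 2:
        raise ValueError("need >=2 pathways to compute a standard deviation")
    return scores.std(axis=0, ddof=1)


_RULES = {
    ("up", "down"): "lost",
    ("down", "up"): "gained",
}


def classify_rewiring(
    normal_enrich: Mapping[str, pd.DataFrame],
    cancer_vs_normal_enrich: Mapping[str, pd.DataFrame],
    frequency_cut: float = 0.20,
) -> dict:
    """Classify each (tissue, pathway) by comparing the pathway's status in
    the normal tissue (vs the average of normals) with its change in the
    matched cancer (vs that normal).

    Rules: a pathway significant in normal that flips direction in cancer is
    "lost" (normal-up & cancer-down) or "gained" (normal-down & cancer-up);
    significant in normal without a flip (cancer not significant, or moving
    the same way) is "maintained"; not significant in normal is "unchanged".

    Inputs are per-tissue enrichment tables from the gsea module (must share
    tissue keys).  Returns a dict with the per-(tissue, pathway) ``table``,
    ``fractions`` per category within each normal-status stratum, and a
    tissue-independent ``frequency`` summary counting pathways significantly
    up/down in more than ``frequency_cut`` of cancers.
    """
    tissues = sorted(normal_enrich)
    if sorted(cancer_vs_normal_enrich) != tissues:
        raise ValueError("normal and cancer enrichment inputs cover different tissues")

    recs = []
    for t in tissues:
        ne = normal_enrich[t]
        ce = cancer_vs_normal_enrich[t]
        for pathway in ne.index.union(ce.index):
            n_call = _status(ne, pathway)
            c_call = _status(ce, pathway)
            if n_call == "ns":
                label = "unchanged"
            else:
                label = _RULES.get((n_call, c_call), "maintained")
            recs.append({"tissue": t, "pathway": pathway,
                         "normal_status": n_call, "cancer_status": c_call,
                         "category": label})
    table = pd.DataFrame(recs)

    sig_in_normal = table[table["normal_status"] != "ns"]
    fractions = (
        sig_in_normal.groupby("normal_status")["category"]
        .value_counts(normalize=True)
        .rename("fraction")
        .reset_index()
    )

    n_cancers = len(tissues)
    freq = (
        table[table["cancer_status"] != "ns"]
        .groupby(["pathway", "cancer_status"])
        .size()
        .rename("n_cancers")
        .reset_index()
    )
    freq["fraction"] = freq["n_cancers"] / n_cancers
    freq["tissue_independent"] = freq["fraction"] > frequency_cut

    return {"table": table, "fractions": fractions, "frequency": freq}


def _status(enrich: pd.DataFrame, pathway: str) -> str:
    if pathway not in enrich.index:
        return "ns"
    call = enrich.loc[pathway, "significant"]
    return {"upregulated": "up", "downregulated": "down"}.get(call, "ns")
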