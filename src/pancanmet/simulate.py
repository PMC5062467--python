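"""Synthetic-data generator for end-to-end testing of the pipeline.

The generator emulates the statistical structure of the real inputs the
pipeline was designed for, at desk scale:

* RNA-seq raw counts: negative-binomial with log-normal baseline means, a
  dispersion trend alpha(mu) = a0 + a1/mu, log-normal library-size factors,
  and pathway-level planted log2 fold changes between conditions (variance
  parameterization: var = mu + alpha mu^2).
* a metabolic signature in which a configurable fraction of genes (~20% by
  default, matching curated metabolic models) belongs to several pathways;
* TCGA-style clinical tables with exponential death times for designated
  low-survival patients and uniform censoring for the rest;
* essentiality matrices with planted tissue-specific shifts (lower = more
  essential);
* metabolite tables linearly coupled to pathway mean expression.

Every operation derives its RNG stream from ``cfg.seed`` plus a fixed
per-operation tag, so a fixed seed gives bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .diffexp import CountMatrix
from .essentiality import EssentialityMatrix
from .signature import MetabolicSignature

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_signature",
    "simulate_cohort",
    "simulate_clinical",
    "simulate_essentiality",
    "simulate_metabolites",
]

_TAGS = {"signature": 1, "cohort": 2, "clinical": 3, "essentiality": 4,
         "metabolites": 5}


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults are sized for desk-scale runs (seconds, one CPU) while keeping
    the moments realistic for bulk RNA-seq: 2000 genes of which 60 pathways
    x ~20 genes are metabolic, 20 normal + 20 tumor samples per tissue,
    log-normal baseline means, a decreasing dispersion trend and planted
    pathway fold changes of |log2FC| 1-1.5.
    """

    seed: int = 0
    # expression universe
    n_genes: int = 2000
    n_pathways: int = 60
    pathway_size: int = 20
    frac_promiscuous: float = 0.20
    extra_memberships: int = 1  # pathways added to each promiscuous gene
    # per-tissue sample counts: tissue -> {condition -> n}
    tissues: Dict[str, Dict[str, int]] = field(
        default_factory=lambda: {"T1": {"normal": 20, "tumor": 20}}
    )
    # NB model
    mean_log: float = 4.0        # natural-log mean of baseline expression
    mean_log_sd: float = 1.5
    disp_a0: float = 0.05        # dispersion trend alpha(mu) = a0 + a1/mu
    disp_a1: float = 2.0
    libsize_log_sd: float = 0.2  # log-normal spread of size factors
    # planted condition effects: pathway -> log2 fold change (tumor vs normal)
    planted_effects: Dict[str, float] = field(
        default_factory=lambda: {"PW01": 1.5, "PW02": 1.0, "PW03": -1.5,
                                 "PW04": -1.0}
    )
    # tissue identity: per-(tissue, pathway) baseline log2 shifts
    tissue_pathway_sd: float = 0.5
    cancer_shift_scale: float = 1.0  # <1 plants cross-tissue convergence in tumors
    # clinical model
    n_patients: int = 200
    frac_low_survival: float = 0.5
    death_scale_years: float = 1.0   # mean of the exponential death time
    followup_max_years: float = 10.0
    # essentiality model
    ess_tissues: Dict[str, int] = field(
        default_factory=lambda: {f"E{i}": 10 for i in range(1, 6)}
    )
    n_shift_genes: int = 50
    ess_shift: float = -3.0   # in units of the score SD
    ess_sd: float = 1.0
    # metabolite model
    metabolite_couplings: List[Tuple[str, str, float]] = field(
        default_factory=lambda: [(f"PW{i:02d}", f"met_{i:02d}", 1.0)
                                 for i in range(1, 6)]
    )
    metabolite_noise_sd: float = 0.5

    def rng(self, op: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, _TAGS[op]])

    def validate(self) -> None:
        if not 0 <= self.frac_promiscuous <= 1:
            raise ValueError("frac_promiscuous must lie in [0, 1]")
        names = {f"PW{i:02d}" for i in range(1, self.n_pathways + 1)}
        for pw in self.planted_effects:
            if pw not in names:
                raise ValueError(f"planted pathway {pw!r} beyond n_pathways")
        for pw, _, _ in self.metabolite_couplings:
            if pw not in names:
                raise ValueError(f"coupled pathway {pw!r} beyond n_pathways")


@dataclass
class GroundTruth:
    pathway_effects: Dict[str, float]
    gene_lfc: pd.Series                      # true log2FC, tumor vs normal
    tissue_shifts: Optional[pd.DataFrame] = None  # pathway x tissue log2 shifts
    low_survival: Optional[set] = None
    high_survival: Optional[set] = None
    shifted_genes: Optional[dict] = None     # gene -> shifted tissue
    couplings: Optional[list] = None


def _gene_names(n):
    return [f"g{i:04d}" for i in range(1, n + 1)]


def simulate_signature(cfg: SimulationConfig) -> MetabolicSignature:
    """Metabolic signature over the first pathway_size * n_pathways genes,
    with a configured fraction of promiscuous (multi-pathway) genes."""
    cfg.validate()
    rng = cfg.rng("signature")
    genes = _gene_names(cfg.n_genes)
    n_sig = cfg.n_pathways * cfg.pathway_size
    if n_sig > cfg.n_genes:
        raise ValueError("signature larger than gene universe")
    sig_genes = genes[:n_sig]
    pathways = {
        f"PW{i + 1:02d}": list(sig_genes[i * cfg.pathway_size:(i + 1) * cfg.pathway_size])
        for i in range(cfg.n_pathways)
    }
    # promiscuity: a random subset of signature genes joins extra pathways
    n_prom = int(round(cfg.frac_promiscuous * n_sig))
    prom_genes = rng.choice(n_sig, size=n_prom, replace=False)
    names = list(pathways)
    for gi in prom_genes:
        g = sig_genes[gi]
        home = gi // cfg.pathway_size
        others = [j for j in range(cfg.n_pathways) if j != home]
        for j in rng.choice(others, size=min(cfg.extra_memberships, len(others)),
                            replace=False):
            if g not in pathways[names[j]]:
                pathways[names[j]].append(g)
    return MetabolicSignature({k: tuple(v) for k, v in pathways.items()})


def _true_gene_lfc(cfg: SimulationConfig, sig: MetabolicSignature) -> pd.Series:
    """Per-gene true log2FC: genes inherit the largest-magnitude planted
    effect among their pathways; background genes are null."""
    lfc = pd.Series(0.0, index=_gene_names(cfg.n_genes))
    for pw, eff in cfg.planted_effects.items():
        if pw not in sig.pathways:
            continue
        for g in sig.pathways[pw]:
            if abs(eff) > abs(lfc[g]):
                lfc[g] = eff
    return lfc


def simulate_cohort(
    cfg: SimulationConfig,
) -> Tuple[CountMatrix, MetabolicSignature, GroundTruth]:
    """NB count matrix across the configured tissues/conditions, with the
    signature and the planted truth."""
    cfg.validate()
    sig = simulate_signature(cfg)
    rng = cfg.rng("cohort")
    genes = _gene_names(cfg.n_genes)
    G = cfg.n_genes

    base_mu = np.exp(rng.normal(cfg.mean_log, cfg.mean_log_sd, size=G))
    alpha = cfg.disp_a0 + cfg.disp_a1 / base_mu
    lfc = _true_gene_lfc(cfg, sig)

    # per-(tissue, pathway) baseline identity shifts, shared by both
    # conditions of a tissue; tumors may have them shrunk (convergence)
    tissue_names = sorted(cfg.tissues)
    shifts = pd.DataFrame(
        rng.normal(0.0, cfg.tissue_pathway_sd,
                   size=(cfg.n_pathways, len(tissue_names))),
        index=[f"PW{i:02d}" for i in range(1, cfg.n_pathways + 1)],
        columns=tissue_names,
    )
    gene_shift = pd.DataFrame(0.0, index=genes, columns=tissue_names)
    for pw, pgenes in sig.pathways.items():
        for g in pgenes:
            # a promiscuous gene takes the largest-magnitude tissue shift
            cur = gene_shift.loc[g]
            cand = shifts.loc[pw]
            upd = cand.abs() > cur.abs()
            gene_shift.loc[g, upd[upd].index] = cand[upd]

    cols, data, meta = [], [], []
    for t in tissue_names:
        for cond, n in sorted(cfg.tissues[t].items()):
            shift = gene_shift[t].values
            if cond != "normal":
                shift = shift * cfg.cancer_shift_scale
            eff = lfc.values if cond != "normal" else np.zeros(G)
            mu_gene = base_mu * 2.0 ** (shift + eff)
            for i in range(n):
                sf = np.exp(rng.normal(0.0, cfg.libsize_log_sd))
                mu = np.maximum(mu_gene * sf, 1e-8)
                lam = rng.gamma(shape=1.0 / alpha, scale=alpha * mu)
                data.append(rng.poisson(lam))
                cols.append(f"{t}_{cond}_{i + 1:03d}")
                meta.append({"sample": cols[-1], "tissue": t,
                             "condition": cond, "cohort": t})
    counts = pd.DataFrame(np.column_stack(data), index=genes, columns=cols)
    sample_meta = pd.DataFrame(meta).set_index("sample")
    truth = GroundTruth(pathway_effects=dict(cfg.planted_effects),
                        gene_lfc=lfc, tissue_shifts=shifts)
    return CountMatrix(counts, sample_meta), sig, truth


def simulate_clinical(cfg: SimulationConfig, cohort: str = "T1"
                      ) -> Tuple[pd.DataFrame, GroundTruth]:
    """TCGA-dialect clinical table: designated low-survival patients die at
    exponential times, the rest are censored alive at uniform times."""
    cfg.validate()
    rng = cfg.rng("clinical")
    n = cfg.n_patients
    ids = [f"{cohort}_pt{i:04d}" for i in range(1, n + 1)]
    n_low = int(round(cfg.frac_low_survival * n))
    low = set(ids[:n_low])
    rows = []
    for pid in ids:
        if pid in low:
            t_death = rng.exponential(cfg.death_scale_years)
            rows.append({"patient": pid, "vital_status": "dead",
                         "days_to_death": round(t_death * 365.25, 1),
                         "days_to_last_followup": np.nan, "cohort": cohort})
        else:
            t_cens = rng.uniform(0.0, cfg.followup_max_years)
            rows.append({"patient": pid, "vital_status": "alive",
                         "days_to_death": np.nan,
                         "days_to_last_followup": round(t_cens * 365.25, 1),
                         "cohort": cohort})
    truth = GroundTruth(pathway_effects={}, gene_lfc=pd.Series(dtype=float),
                        low_survival=low, high_survival=set(ids) - low)
    return pd.DataFrame(rows), truth


def simulate_essentiality(cfg: SimulationConfig
                          ) -> Tuple[EssentialityMatrix, MetabolicSignature, GroundTruth]:
    """Essentiality score matrix over the metabolic genes, with planted
    tissue-specific shifts (lower score = more essential)."""
    cfg.validate()
    if len(cfg.ess_tissues) < 2:
        raise ValueError("need >=2 tissues")
    sig = simulate_signature(cfg)
    rng = cfg.rng("essentiality")
    genes = sorted(sig.genes)
    tissues = sorted(cfg.ess_tissues)
    lines, tmap = [], {}
    for t in tissues:
        for i in range(cfg.ess_tissues[t]):
            cl = f"{t}_cl{i + 1:02d}"
            lines.append(cl)
            tmap[cl] = t

    baseline = rng.normal(0.0, 1.0, size=len(genes))
    X = baseline[:, None] + rng.normal(0.0, cfg.ess_sd,
                                       size=(len(genes), len(lines)))
    shifted_idx = rng.choice(len(genes), size=cfg.n_shift_genes, replace=False)
    shifted = {}
    for gi in shifted_idx:
        t = tissues[int(rng.integers(len(tissues)))]
        shifted[genes[gi]] = t
        cols = [j for j, cl in enumerate(lines) if tmap[cl] == t]
        X[gi, cols] += cfg.ess_shift * cfg.ess_sd
    scores = pd.DataFrame(X, index=genes, columns=lines)
    truth = GroundTruth(pathway_effects={}, gene_lfc=pd.Series(dtype=float),
                        shifted_genes=shifted)
    return EssentialityMatrix(scores, pd.Series(tmap)), sig, truth


def simulate_metabolites(cfg: SimulationConfig, counts: CountMatrix,
                         sig: MetabolicSignature
                         ) -> Tuple[pd.DataFrame, GroundTruth]:
    """Metabolite abundances linearly coupled to pathway mean expression
    (on the log2 normalized-count scale) plus Gaussian noise."""
    cfg.validate()
    rng = cfg.rng("metabolites")
    expr = np.log2(counts.counts / counts.counts.sum(axis=0) * 1e6 + 1.0)
    rows = {}
    for pw, met, beta in cfg.metabolite_couplings:
        if pw not in sig.pathways:
            continue
        pm = expr.loc[[g for g in sig.pathways[pw] if g in expr.index]].mean(axis=0)
        rows[met] = beta * pm + rng.normal(0.0, cfg.metabolite_noise_sd, size=len(pm))
    table = pd.DataFrame(rows).T
    truth = GroundTruth(pathway_effects={}, gene_lfc=pd.Series(dtype=float),
                        couplings=list(cfg.metabolite_couplings))
    return table, truth
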