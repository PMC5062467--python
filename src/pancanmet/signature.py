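"""Metabolic gene signature: pathway membership, gene promiscuity and the
promiscuity correction of gene-level statistics.

A metabolic signature maps pathways to gene sets, derived from a genome-scale
metabolic model.  Because the metabolic network is interconnected, a sizeable
fraction of genes (about 20% in curated signatures) belongs to more than one
pathway; such *promiscuous* genes can drive spurious pathway-level enrichment.
The correction implemented here divides each gene's differential-expression
statistic by its number of pathway memberships so that a gene shared by k
pathways contributes 1/k of its evidence to each.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Mapping, Tuple

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "MetabolicSignature",
    "GMTParseError",
    "read_gmt",
    "write_gmt",
    "compute_promiscuity",
    "correct_statistic",
]


class GMTParseError(ValueError):
    """Raised when a GMT file is malformed."""


@dataclass(frozen=True)
class MetabolicSignature:
    """Pathway -> gene mapping with the derived gene -> pathways inverse.

    ``pathways`` maps pathway name to an ordered, duplicate-free tuple of gene
    identifiers; ``gene_index`` is its exact inverse.
    """

    pathways: Dict[str, Tuple[str, ...]]
    descriptions: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for name, genes in self.pathways.items():
            if len(genes) == 0:
                raise ValueError(f"pathway {name!r} has an empty gene list")
            if len(set(genes)) != len(genes):
                raise ValueError(f"pathway {name!r} contains duplicate genes")

    @property
    def gene_index(self) -> Dict[str, frozenset]:
        index: Dict[str, set] = {}
        for name, genes in self.pathways.items():
            for g in genes:
                index.setdefault(g, set()).add(name)
        return {g: frozenset(ps) for g, ps in index.items()}

    @property
    def genes(self) -> frozenset:
        return frozenset(g for genes in self.pathways.values() for g in genes)

    def __len__(self) -> int:
        return len(self.pathways)

    def subset(self, genes) -> "MetabolicSignature":
        """Restrict every pathway to the given gene universe, dropping pathways
        left empty."""
        keep = set(genes)
        new = {
            name: tuple(g for g in gs if g in keep)
            for name, gs in self.pathways.items()
        }
        new = {name: gs for name, gs in new.items() if gs}
        return MetabolicSignature(new, dict(self.descriptions))


def read_gmt(path) -> MetabolicSignature:
    """Parse a Broad-dialect GMT file (name, description, tab-separated genes).

    Duplicate genes within a set are deduplicated with a logged warning.
    Raises :class:`GMTParseError` naming the offending line for malformed
    input, and for an empty file.
    """
    path = Path(path)
    pathways: Dict[str, Tuple[str, ...]] = {}
    descriptions: Dict[str, str] = {}
    with open(path) as fh:
        n_lines = 0
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            n_lines += 1
            fields = line.split("\t")
            if len(fields) < 3:
                raise GMTParseError(
                    f"{path}:{lineno}: expected >=3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            name, desc = fields[0].strip(), fields[1]
            genes_raw = [g.strip() for g in fields[2:] if g.strip()]
            if not name or not genes_raw:
                raise GMTParseError(f"{path}:{lineno}: empty pathway name or gene list")
            seen, genes = set(), []
            for g in genes_raw:
                if g in seen:
                    logger.warning(
                        "GMT %s line %d: duplicated gene %r in set %r deduplicated",
                        path, lineno, g, name,
                    )
                else:
                    seen.add(g)
                    genes.append(g)
            if name in pathways:
                raise GMTParseError(f"{path}:{lineno}: duplicate pathway name {name!r}")
            pathways[name] = tuple(genes)
            descriptions[name] = desc
    if n_lines == 0:
        raise GMTParseError(f"{path}: empty GMT file")
    return MetabolicSignature(pathways, descriptions)


def write_gmt(sig: MetabolicSignature, path) -> None:
    """Write a signature back to GMT."""
    with open(path, "w") as fh:
        for name, genes in sig.pathways.items():
            desc = sig.descriptions.get(name, "na") or "na"
            fh.write("\t".join([name, desc, *genes]) + "\n")


def compute_promiscuity(sig: MetabolicSignature) -> pd.Series:
    """Number of pathways each signature gene belongs to (>= 1)."""
    if len(sig) == 0:
        raise ValueError("empty signature")
    index = sig.gene_index
    return pd.Series({g: len(ps) for g, ps in index.items()}, dtype=int).sort_index()


def correct_statistic(stats: Mapping[str, float], prom: pd.Series) -> pd.Series:
    """Divide each gene's statistic by its promiscuity.

    Genes absent from the signature are dropped (their count is logged): the
    analysis concerns metabolic genes only.  The sign of every statistic is
    preserved, and promiscuity-1 genes pass through unchanged.
    """
    s = pd.Series(dict(stats)) if not isinstance(stats, pd.Series) else stats
    in_sig = s.index.intersection(prom.index)
    n_dropped = len(s) - len(in_sig)
    if n_dropped:
        logger.info("correct_statistic: dropped %d genes absent from signature", n_dropped)
    s = s.loc[in_sig]
    return s / prom.loc[in_sig].astype(float)
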