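"""TSV plumbing shared by the command-line layer.

All tabular interchange is tab-separated text: count matrices (first column
gene id, header sample ids), sample annotation tables, TCGA-style clinical
tables, essentiality score matrices and two-column pairing files.  Gene-set
interchange is GMT (see :mod:`pancanmet.signature`).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .diffexp import CountMatrix
from .essentiality import EssentialityMatrix

__all__ = [
    "read_counts",
    "write_counts",
    "read_clinical",
    "read_essentiality",
    "read_pairing",
    "write_table",
]


def read_counts(counts_path, annotations_path=None) -> CountMatrix:
    """Count matrix TSV (+ optional sample-annotation TSV with columns
    sample, tissue, condition[, cohort])."""
    mat = pd.read_csv(counts_path, sep="\t", index_col=0)
    meta = None
    if annotations_path is not None:
        meta = pd.read_csv(annotations_path, sep="\t")
        meta = meta.set_index("sample")
        if "cohort" not in meta.columns:
            meta["cohort"] = meta["tissue"]
    return CountMatrix(mat, meta)


def write_counts(cm: CountMatrix, counts_path, annotations_path=None) -> None:
    cm.counts.to_csv(counts_path, sep="\t", index_label="gene")
    if annotations_path is not None:
        cm.sample_meta.to_csv(annotations_path, sep="\t", index_label="sample")


def read_clinical(path) -> pd.DataFrame:
    """TCGA-style clinical TSV: patient, vital_status, days_to_death,
    days_to_last_followup[, cohort]."""
    return pd.read_csv(path, sep="\t")


def read_essentiality(scores_path, map_path) -> EssentialityMatrix:
    """Score matrix TSV (gene rows, cell-line columns) and a two-column
    cell-line -> tissue map TSV."""
    scores = pd.read_csv(scores_path, sep="\t", index_col=0)
    m = pd.read_csv(map_path, sep="\t")
    tmap = pd.Series(m.iloc[:, 1].values, index=m.iloc[:, 0].values)
    return EssentialityMatrix(scores, tmap)


def read_pairing(path) -> dict:
    """Two-column TSV mapping normal tissue to cancer cohort."""
    m = pd.read_csv(path, sep="\t")
    return dict(zip(m.iloc[:, 0], m.iloc[:, 1]))


def write_table(df: pd.DataFrame, path, index_label=None) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index_label=index_label)
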