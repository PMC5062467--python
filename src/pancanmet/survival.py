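"""Survival-based patient stratification.

Patients are split into a "high survival" group — censored alive for longer
than the 75th percentile of the cohort's observed follow-up times — and a
"low survival" group — dead before that same threshold.  Patients matching
neither rule (alive with short follow-up, dead late, or sitting exactly on
the threshold) are excluded with a reason, and cohorts in which either group
ends up smaller than 5 patients are dropped from downstream expression
analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["SurvivalGroups", "clinical_table", "stratify", "exclude_cohorts"]

DAYS_PER_YEAR = 365.25


@dataclass
class SurvivalGroups:
    high: set
    low: set
    threshold_years: float
    excluded: Dict[str, str] = field(default_factory=dict)  # patient -> reason


def clinical_table(df: pd.DataFrame, days_per_year: float = DAYS_PER_YEAR) -> pd.DataFrame:
    """Normalize a TCGA-style clinical frame into (patient, status, time_years,
    cohort).

    Expects columns ``patient`` (or index), ``vital_status`` ("alive"/"dead",
    case-insensitive), ``days_to_death``, ``days_to_last_followup`` and
    optionally ``cohort``.  Death time is authoritative for dead patients;
    follow-up time is used for the living.
    """
    d = df.copy()
    if "patient" in d.columns:
        d = d.set_index("patient")
    status = d["vital_status"].astype(str).str.strip().str.lower()
    days_death = pd.to_numeric(d.get("days_to_death"), errors="coerce")
    days_fu = pd.to_numeric(d.get("days_to_last_followup"), errors="coerce")
    time_days = np.where(status == "dead", days_death, days_fu)
    out = pd.DataFrame(
        {
            "vital_status": status,
            "time_years": time_days / days_per_year,
            "cohort": d["cohort"] if "cohort" in d.columns else "na",
        },
        index=d.index,
    )
    return out


def stratify(clin: pd.DataFrame, quantile: float = 0.75) -> SurvivalGroups:
    """Apply the percentile stratification rule to one cohort.

    ``clin`` must carry ``vital_status`` in {"alive", "dead"} and
    ``time_years``; the threshold is the linear-interpolation (type-7)
    quantile of all patients' observed times.  Membership is strict:
    high = alive with time > threshold, low = dead with time < threshold;
    boundary patients and rule mismatches are excluded with a reason.
    """
    status = clin["vital_status"].astype(str).str.strip().str.lower()
    time = pd.to_numeric(clin["time_years"], errors="coerce")

    excluded: Dict[str, str] = {}
    valid_status = status.isin(["alive", "dead"])
    for p in clin.index[~valid_status]:
        excluded[p] = "missing-status"
    valid = valid_status & time.notna()
    for p in clin.index[valid_status & time.isna()]:
        excluded[p] = "missing-time"

    times = time[valid]
    if len(times) == 0:
        raise ValueError("no patient has an observed time")
    if len(times) < 4:
        raise ValueError("need >=4 patients with valid times")
    threshold = float(np.quantile(times.values, quantile))  # type-7 default

    high, low = set(), set()
    for p in clin.index[valid]:
        t = time[p]
        if status[p] == "alive":
            if t > threshold:
                high.add(p)
            elif t == threshold:
                excluded[p] = "boundary"
            else:
                excluded[p] = "alive-short-followup"
        else:
            if t < threshold:
                low.add(p)
            elif t == threshold:
                excluded[p] = "boundary"
            else:
                excluded[p] = "dead-late"
    return SurvivalGroups(high=high, low=low, threshold_years=threshold,
                          excluded=excluded)


def exclude_cohorts(groups: Mapping[str, SurvivalGroups], min_n: int = 5) -> list:
    """Retain cohorts whose high and low groups both have >= ``min_n``
    patients; dropped cohorts are logged."""
    retained = []
    for cohort, g in groups.items():
        if len(g.high) >= min_n and len(g.low) >= min_n:
            retained.append(cohort)
        else:
            logger.info(
                "cohort %s dropped: high=%d low=%d (min_n=%d)",
                cohort, len(g.high), len(g.low), min_n,
            )
    return retained
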