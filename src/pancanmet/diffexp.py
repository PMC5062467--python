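"""Differential expression between two sample groups.

Two paths are provided, matching the two kinds of input the pipeline meets:

* :func:`nb_wald_test` — a negative-binomial (NB) generalized linear model
  with log link for raw RNA-seq counts.  Library depth is handled through
  median-of-ratios size factors used as offsets; gene-wise dispersions are
  estimated by Cox-Reid-adjusted maximum likelihood, moderated toward a
  parametric trend alpha(mu) = a0 + a1/mu via a log-normal prior, and the
  group coefficient is tested with a Wald z-statistic.

* :func:`ttest_pipeline` — a normality-checked Welch t-test for continuous
  expression matrices (microarray-style validation cohorts): a Shapiro-Wilk
  p-value is recorded per gene as a QC field and a two-sided unequal-variance
  t-test provides the statistic.

Both paths adjust p-values across genes with Benjamini-Hochberg.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from ._stats import bh_adjust

logger = logging.getLogger(__name__)

__all__ = [
    "CountMatrix",
    "size_factors",
    "nb_wald_test",
    "ttest_pipeline",
    "fit_dispersion_trend",
]

_MIN_DISP = 1e-8
_MAX_DISP = 30.0


@dataclass
class CountMatrix:
    """Raw integer counts (genes x samples) plus per-sample annotations.

    ``sample_meta`` is indexed by sample identifier and must provide at least
    ``tissue`` and ``condition`` columns; ``cohort`` is optional.
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame = None

    def __post_init__(self):
        c = self.counts
        if (np.asarray(c.values) < 0).any():
            raise ValueError("counts contain negative entries")
        if c.index.duplicated().any():
            raise ValueError("gene identifiers are not unique")
        if self.sample_meta is None:
            self.sample_meta = pd.DataFrame(
                {"tissue": "na", "condition": "na", "cohort": "na"}, index=c.columns
            )
        missing = c.columns.difference(self.sample_meta.index)
        if len(missing):
            raise ValueError(f"samples without annotations: {list(missing)[:5]}")
        for col in ("tissue", "condition"):
            if col not in self.sample_meta.columns:
                raise ValueError(f"sample_meta lacks required column {col!r}")

    @property
    def genes(self):
        return self.counts.index

    @property
    def samples(self):
        return self.counts.columns

    def samples_where(self, **conditions) -> list:
        """Sample ids whose metadata match all given column=value filters."""
        meta = self.sample_meta.loc[self.counts.columns]
        mask = np.ones(len(meta), dtype=bool)
        for col, val in conditions.items():
            mask &= (meta[col] == val).values
        return list(meta.index[mask])


# ---------------------------------------------------------------------------
# size factors (median-of-ratios)
# ---------------------------------------------------------------------------

def size_factors(counts, pseudo_reference: bool = False) -> pd.Series:
    """Median-of-ratios size factors.

    The reference is the per-gene geometric mean across samples; genes with a
    zero anywhere drop out of the reference.  If no gene is expressed in all
    samples, an error advises the ``pseudo_reference`` fallback, which forms
    the reference from log(count + 0.5) instead.
    """
    mat = counts.counts if isinstance(counts, CountMatrix) else counts
    x = np.asarray(mat.values, dtype=float)
    if pseudo_reference:
        ref = np.exp(np.log(x + 0.5).mean(axis=1))
        sf = np.median((x + 0.5) / ref[:, None], axis=0)
    else:
        with np.errstate(divide="ignore"):
            logx = np.log(x)
        logref = logx.mean(axis=1)  # -inf for genes with any zero
        ok = np.isfinite(logref)
        if not ok.any():
            raise ValueError(
                "no gene has nonzero counts in every sample; "
                "re-run with pseudo_reference=True"
            )
        sf = np.median(x[ok] / np.exp(logref[ok])[:, None], axis=0)
    return pd.Series(sf, index=mat.columns, name="size_factor")


# ---------------------------------------------------------------------------
# NB GLM internals (vectorized across genes)
# ---------------------------------------------------------------------------

def _irls_nb(y, x, offset, alpha, n_iter=50, tol=1e-10):
    """Fit per-gene NB GLM, log link, design [1, x], given dispersions.

    y: (G, n) counts; x: (n,) 0/1 indicator; offset: (n,) log size factors;
    alpha: (G,) dispersions.  Returns beta (G, 2) on the natural-log scale
    and the 2x2 weighted information pieces needed for standard errors.
    """
    G, n = y.shape
    alpha = np.broadcast_to(np.asarray(alpha, float), (G,))
    # moment-based start: log of offset-adjusted group means
    w0, w1 = (x == 0), (x == 1)
    adj = y / np.exp(offset)[None, :]
    m0 = adj[:, w0].mean(axis=1) + 0.1
    m1 = adj[:, w1].mean(axis=1) + 0.1
    beta = np.column_stack([np.log(m0), np.log(m1) - np.log(m0)])
    xb = x[None, :]
    for _ in range(n_iter):
        eta = beta[:, [0]] + beta[:, [1]] * xb + offset[None, :]
        mu = np.exp(np.clip(eta, -30, 30))
        W = mu / (1.0 + alpha[:, None] * mu)
        z = (eta - offset[None, :]) + (y - mu) / mu
        # 2x2 normal equations, elementwise across genes
        s00 = W.sum(axis=1)
        s01 = (W * xb).sum(axis=1)
        s11 = (W * xb * xb).sum(axis=1)
        t0 = (W * z).sum(axis=1)
        t1 = (W * z * xb).sum(axis=1)
        det = s00 * s11 - s01 * s01
        det = np.where(np.abs(det) < 1e-300, 1e-300, det)
        b0 = (s11 * t0 - s01 * t1) / det
        b1 = (s00 * t1 - s01 * t0) / det
        new = np.column_stack([b0, b1])
        delta = np.nanmax(np.abs(new - beta))
        beta = new
        if delta < tol:
            break
    eta = beta[:, [0]] + beta[:, [1]] * xb + offset[None, :]
    mu = np.exp(np.clip(eta, -30, 30))
    W = mu / (1.0 + alpha[:, None] * mu)
    s00 = W.sum(axis=1)
    s01 = (W * xb).sum(axis=1)
    s11 = (W * xb * xb).sum(axis=1)
    det = s00 * s11 - s01 * s01
    se1 = np.sqrt(np.where(det > 0, s00 / np.maximum(det, 1e-300), np.nan))
    return beta, mu, se1


def _nb_loglik(y, mu, log_alpha, x):
    """Cox-Reid-adjusted NB log-likelihood, vectorized over genes.

    log_alpha: (G,) candidate log dispersions. Returns (G,) values.
    """
    alpha = np.exp(log_alpha)[:, None]
    inv = 1.0 / alpha
    ll = (
        special.gammaln(y + inv)
        - special.gammaln(inv)
        - special.gammaln(y + 1.0)
        + y * np.log(alpha * mu / (1.0 + alpha * mu))
        - inv * np.log1p(alpha * mu)
    ).sum(axis=1)
    # Cox-Reid term: -0.5 log det(X' W X) for design [1, group]
    W = mu / (1.0 + alpha * mu)
    xb = x[None, :]
    s00 = W.sum(axis=1)
    s01 = (W * xb).sum(axis=1)
    s11 = (W * xb * xb).sum(axis=1)
    det = np.maximum(s00 * s11 - s01 * s01, 1e-300)
    return ll - 0.5 * np.log(det)


def _maximize_log_alpha(objective, G, lo=np.log(_MIN_DISP), hi=np.log(_MAX_DISP), iters=60):
    """Vectorized golden-section maximization of a per-gene 1-D objective."""
    gr = (np.sqrt(5.0) - 1.0) / 2.0
    a = np.full(G, lo)
    b = np.full(G, hi)
    c = b - gr * (b - a)
    d = a + gr * (b - a)
    fc = objective(c)
    fd = objective(d)
    for _ in range(iters):
        shrink_right = fc > fd  # max in [a, d]
        b = np.where(shrink_right, d, b)
        a = np.where(shrink_right, a, c)
        c = b - gr * (b - a)
        d = a + gr * (b - a)
        fc = objective(c)
        fd = objective(d)
    return (a + b) / 2.0


def fit_dispersion_trend(mean_norm, disp, min_used=10):
    """Fit the parametric dispersion-mean trend alpha(mu) = a0 + a1/mu.

    A gamma-family iteratively reweighted least-squares fit (weights
    1/fitted^2), with outlier genes (>1e4-fold off the current fit) excluded,
    mirroring the standard parametric trend fit for RNA-seq dispersions.
    Returns (a0, a1); raises RuntimeError when too few usable genes remain.
    """
    mu = np.asarray(mean_norm, float)
    d = np.asarray(disp, float)
    ok = np.isfinite(mu) & np.isfinite(d) & (mu > 0) & (d > 10 * _MIN_DISP)
    if ok.sum() < min_used:
        raise RuntimeError("too few genes with usable dispersion estimates")
    mu, d = mu[ok], d[ok]
    X = np.column_stack([np.ones_like(mu), 1.0 / mu])
    use = np.ones(len(d), dtype=bool)
    a = np.array([np.median(d), 0.0])
    for _ in range(10):
        fitted = np.maximum(X @ a, 1e-12)
        ratio = d / fitted
        use = (ratio < 1e4) & (ratio > 1e-4)
        if use.sum() < min_used:
            break
        w = 1.0 / fitted[use] ** 2
        Xu, du = X[use], d[use]
        A = (Xu * w[:, None]).T @ Xu
        b = (Xu * w[:, None]).T @ du
        try:
            new = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            break
        if np.allclose(new, a, rtol=1e-6):
            a = new
            break
        a = new
    a0 = max(float(a[0]), _MIN_DISP)
    a1 = max(float(a[1]), 0.0)
    return a0, a1


def _estimate_dispersions(y, x, offset, shrink=True):
    """Gene-wise CR-adjusted ML dispersions, parametric trend, and MAP
    moderation toward the trend under a log-normal prior.

    Returns (alpha_final, alpha_genewise, (a0, a1) or None).
    """
    G, n = y.shape
    # initial moment estimate on normalized counts
    q = y / np.exp(offset)[None, :]
    m = q.mean(axis=1)
    v = q.var(axis=1, ddof=1)
    alpha0 = np.clip((v - m) / np.maximum(m, 1e-8) ** 2, _MIN_DISP, _MAX_DISP)
    beta, mu, _ = _irls_nb(y, x, offset, alpha0)

    def obj_ml(la):
        return _nb_loglik(y, mu, la, x)

    la_gw = _maximize_log_alpha(obj_ml, G)
    # one refit of the means with the gene-wise dispersions
    beta, mu, _ = _irls_nb(y, x, offset, np.exp(la_gw))
    la_gw = _maximize_log_alpha(obj_ml, G)
    alpha_gw = np.exp(la_gw)

    if not shrink:
        return alpha_gw, alpha_gw, None

    try:
        a0, a1 = fit_dispersion_trend(m, alpha_gw)
    except RuntimeError:
        logger.warning("dispersion trend fit failed; using gene-wise dispersions")
        return alpha_gw, alpha_gw, None
    trend = np.clip(a0 + a1 / np.maximum(m, 1e-8), _MIN_DISP, _MAX_DISP)
    log_trend = np.log(trend)
    # prior width: spread of log residuals beyond estimation noise
    resid = la_gw - log_trend
    usable = alpha_gw > 10 * _MIN_DISP
    s_lr = (
        stats.median_abs_deviation(resid[usable], scale="normal")
        if usable.sum() >= 3
        else 1.0
    )
    sampling_var = special.polygamma(1, (n - 2) / 2.0)
    prior_var = max(s_lr**2 - sampling_var, 0.25)

    def obj_map(la):
        return _nb_loglik(y, mu, la, x) - (la - log_trend) ** 2 / (2 * prior_var)

    la_map = _maximize_log_alpha(obj_map, G)
    alpha = np.exp(la_map)
    # dispersion outliers (far above the trend) keep their gene-wise value
    outlier = resid > 2.0 * np.sqrt(prior_var + sampling_var) + np.log(10)
    alpha[outlier] = alpha_gw[outlier]
    return alpha, alpha_gw, (a0, a1)


# ---------------------------------------------------------------------------
# public tests
# ---------------------------------------------------------------------------

def nb_wald_test(
    counts: CountMatrix,
    groupA: Sequence[str],
    groupB: Sequence[str],
    dispersion: str = "trended",
    pseudo_reference: bool = False,
) -> pd.DataFrame:
    """NB GLM Wald test of group B vs group A.

    Design: intercept + group indicator, log size-factor offsets.  Returns a
    DataFrame indexed by gene with columns ``baseMean``, ``log2FoldChange``
    (B vs A), ``lfcSE``, ``stat``, ``pvalue``, ``padj``.  All-zero genes get
    NaN statistics and are excluded from the BH adjustment.

    ``dispersion='gene-wise-only'`` disables the shrinkage toward the
    parametric trend.
    """
    groupA, groupB = list(groupA), list(groupB)
    if len(groupA) < 2 or len(groupB) < 2:
        raise ValueError("each group needs >=2 samples to estimate dispersion")
    if set(groupA) & set(groupB):
        raise ValueError("groups overlap")
    if dispersion not in ("trended", "gene-wise-only"):
        raise ValueError(f"unknown dispersion mode {dispersion!r}")

    mat = counts.counts[groupA + groupB]
    sf = size_factors(CountMatrix(mat), pseudo_reference=pseudo_reference)
    offset = np.log(sf.values)
    x = np.array([0] * len(groupA) + [1] * len(groupB), dtype=float)
    y_all = np.asarray(mat.values, dtype=float)

    nonzero = y_all.sum(axis=1) > 0
    y = y_all[nonzero]
    out = pd.DataFrame(
        np.nan,
        index=mat.index,
        columns=["baseMean", "log2FoldChange", "lfcSE", "stat", "pvalue", "padj"],
    )
    out["baseMean"] = (y_all / np.exp(offset)[None, :]).mean(axis=1)
    if nonzero.sum() == 0:
        return out

    alpha, _, _ = _estimate_dispersions(
        y, x, offset, shrink=(dispersion == "trended")
    )
    beta, mu, se1 = _irls_nb(y, x, offset, alpha)
    wald = beta[:, 1] / se1
    pval = 2.0 * stats.norm.sf(np.abs(wald))

    ln2 = np.log(2.0)
    out.loc[nonzero, "log2FoldChange"] = beta[:, 1] / ln2
    out.loc[nonzero, "lfcSE"] = se1 / ln2
    out.loc[nonzero, "stat"] = wald
    out.loc[nonzero, "pvalue"] = pval
    out["padj"] = bh_adjust(out["pvalue"].values)
    logger.info(
        "nb_wald_test: %d genes tested, %d all-zero genes excluded",
        int(nonzero.sum()), int((~nonzero).sum()),
    )
    return out


def ttest_pipeline(
    expr: pd.DataFrame, groupA: Sequence[str], groupB: Sequence[str]
) -> pd.DataFrame:
    """Shapiro-Wilk QC followed by a two-sided Welch t-test per gene.

    The Shapiro-Wilk p-value is computed on group-centred residuals and
    recorded as a QC column; every gene is still tested (no branch on the
    normality outcome).  Genes with zero variance in both groups get NaN and
    are excluded from the BH adjustment.
    """
    groupA, groupB = list(groupA), list(groupB)
    if len(groupA) < 3 or len(groupB) < 3:
        raise ValueError("each group needs >=3 samples")
    a = expr[groupA].values.astype(float)
    b = expr[groupB].values.astype(float)

    var_a = a.var(axis=1, ddof=1)
    var_b = b.var(axis=1, ddof=1)
    testable = (var_a + var_b) > 0

    tstat = np.full(len(expr), np.nan)
    pval = np.full(len(expr), np.nan)
    res = stats.ttest_ind(
        b[testable], a[testable], axis=1, equal_var=False
    )  # sign: B vs A
    tstat[testable] = res.statistic
    pval[testable] = res.pvalue

    sw = np.full(len(expr), np.nan)
    resid = np.column_stack([a - a.mean(axis=1, keepdims=True),
                             b - b.mean(axis=1, keepdims=True)])
    for i in np.where(testable)[0]:
        r = resid[i]
        if np.ptp(r) > 0:
            sw[i] = stats.shapiro(r).pvalue

    out = pd.DataFrame(
        {
            "meanA": a.mean(axis=1),
            "meanB": b.mean(axis=1),
            "log2FoldChange": b.mean(axis=1) - a.mean(axis=1),
            "stat": tstat,
            "pvalue": pval,
            "shapiro_p": sw,
        },
        index=expr.index,
    )
    out["padj"] = bh_adjust(out["pvalue"].values)
    return out
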