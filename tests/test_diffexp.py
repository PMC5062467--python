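import numpy as np
import pandas as pd
import pytest
from scipy import stats as ss

from pancanmet._stats import bh_adjust
from pancanmet.diffexp import (CountMatrix, _irls_nb, nb_wald_test,
                               size_factors, ttest_pipeline)
from conftest import make_counts


SAMPLES6 = [f"s{j}" for j in range(6)]


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        col = pd.Series([3, 10, 250, 7], index=list("abcd"))
        mat = pd.DataFrame({"s1": col, "s2": col})
        sf = size_factors(mat)
        assert np.allclose(sf.values, [1.0, 1.0])

    def test_column_scaling(self):
        rng = np.random.default_rng(0)
        c1 = rng.integers(1, 300, 40)
        mat = pd.DataFrame({"s1": c1, "s2": 2 * c1})
        sf = size_factors(mat)
        assert np.isclose(sf["s2"] / sf["s1"], 2.0)

    def test_matches_reference_loop(self):
        rng = np.random.default_rng(1)
        mat = make_counts(rng, 50, SAMPLES6)
        sf = size_factors(mat)
        # brute force: per-gene geometric-mean reference, median of ratios
        x = mat.values.astype(float)
        ok = (x > 0).all(axis=1)
        geo = np.exp(np.log(x[ok]).mean(axis=1))
        for j, s in enumerate(mat.columns):
            ratios = sorted(x[ok, j] / geo)
            k = len(ratios)
            med = (ratios[k // 2] if k % 2 else
                   0.5 * (ratios[k // 2 - 1] + ratios[k // 2]))
            assert np.isclose(sf[s], med)

    def test_no_common_gene_errors_and_pseudo_reference(self):
        mat = pd.DataFrame({"s1": [5, 0], "s2": [0, 7]}, index=["a", "b"])
        with pytest.raises(ValueError, match="pseudo_reference"):
            size_factors(mat)
        sf = size_factors(mat, pseudo_reference=True)
        assert (sf > 0).all()


class TestNBWald:
    def test_group_size_and_overlap_validation(self):
        rng = np.random.default_rng(2)
        cm = CountMatrix(make_counts(rng, 20, SAMPLES6))
        with pytest.raises(ValueError, match=">=2"):
            nb_wald_test(cm, SAMPLES6[:1], SAMPLES6[1:])
        with pytest.raises(ValueError, match="overlap"):
            nb_wald_test(cm, SAMPLES6[:3], SAMPLES6[2:])

    def test_gene_row_order_invariance(self):
        rng = np.random.default_rng(3)
        mat = make_counts(rng, 60, SAMPLES6)
        de1 = nb_wald_test(CountMatrix(mat), SAMPLES6[:3], SAMPLES6[3:])
        perm = rng.permutation(len(mat))
        de2 = nb_wald_test(CountMatrix(mat.iloc[perm]), SAMPLES6[:3], SAMPLES6[3:])
        pd.testing.assert_frame_equal(de1, de2.loc[de1.index])

    def test_all_zero_genes_na_and_excluded_from_bh(self):
        rng = np.random.default_rng(4)
        mat = make_counts(rng, 30, SAMPLES6)
        mat.iloc[5] = 0
        de = nb_wald_test(CountMatrix(mat), SAMPLES6[:3], SAMPLES6[3:])
        assert np.isnan(de.iloc[5]["stat"]) and np.isnan(de.iloc[5]["padj"])
        assert de["pvalue"].notna().sum() == 29

    def test_sample_scaling_moves_size_factor_not_statistics(self):
        """Depth is absorbed by the offset: tripling one sample's counts
        triples its relative size factor and leaves the Wald statistics
        essentially unchanged (the raw-count likelihood weighting shifts
        slightly, so the agreement is approximate, not exact)."""
        rng = np.random.default_rng(5)
        samples = [f"s{j}" for j in range(12)]
        mat = make_counts(rng, 200, samples, mu_range=(20, 500))
        de1 = nb_wald_test(CountMatrix(mat), samples[:6], samples[6:])
        mat2 = mat.copy()
        mat2["s0"] = mat["s0"] * 3
        de2 = nb_wald_test(CountMatrix(mat2), samples[:6], samples[6:])
        sf1, sf2 = size_factors(mat), size_factors(mat2)
        rel1 = sf1 / sf1["s3"]
        rel2 = sf2 / sf2["s3"]
        assert np.isclose(rel2["s0"] / rel1["s0"], 3.0)
        assert (de2["stat"] - de1["stat"]).abs().max() < 0.2

    def test_poisson_limit_matches_poisson_glm(self):
        """With dispersion forced to ~0 the NB Wald statistic reduces to the
        Poisson GLM Wald statistic."""
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(6)
        G, n = 40, 12
        y = rng.poisson(rng.uniform(5, 200, size=(G, 1)),
                        size=(G, n)).astype(float)
        x = np.array([0.0] * 6 + [1.0] * 6)
        off = np.log(rng.uniform(0.7, 1.4, n))
        beta, _, se1 = _irls_nb(y, x, off, np.full(G, 1e-10))
        wald = beta[:, 1] / se1
        X = sm.add_constant(x)
        for i in range(G):
            fit = sm.GLM(y[i], X, family=sm.families.Poisson(), offset=off).fit()
            assert abs(wald[i] - fit.params[1] / fit.bse[1]) < 0.01 * abs(
                fit.params[1] / fit.bse[1]
            ) + 1e-8

    def test_agrees_with_independent_nb_glm_implementation(self):
        """Dual-route check of the whole Wald pipeline (size factors,
        dispersion trend + shrinkage, GLM fit) against an independently
        developed NB Wald implementation on a planted-effect fixture."""
        pydeseq2 = pytest.importorskip("pydeseq2")
        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.ds import DeseqStats

        rng = np.random.default_rng(3)
        G, n = 200, 12
        mu = rng.uniform(20, 500, G)
        lam = rng.gamma(10, 0.1 * mu[:, None], size=(G, n))
        y = rng.poisson(lam)
        y[:20, 6:] = rng.poisson(
            rng.gamma(10, 0.1 * mu[:20, None] * 2.5, size=(20, 6)))
        counts = pd.DataFrame(y.T, columns=[f"g{i}" for i in range(G)])
        meta = pd.DataFrame({"condition": ["A"] * 6 + ["B"] * 6})
        dds = DeseqDataSet(counts=counts, metadata=meta, design="~condition",
                           quiet=True)
        dds.deseq2()
        ref = DeseqStats(dds, contrast=["condition", "B", "A"], quiet=True)
        ref.summary()
        samples = [f"s{j}" for j in range(n)]
        cm = CountMatrix(pd.DataFrame(y, index=[f"g{i}" for i in range(G)],
                                      columns=samples))
        de = nb_wald_test(cm, samples[:6], samples[6:])
        r = ss.pearsonr(de["stat"].values, ref.results_df["stat"].values)[0]
        assert r > 0.999
        assert np.allclose(de["log2FoldChange"].values,
                           ref.results_df["log2FoldChange"].values, atol=0.05)


class TestTTest:
    def test_equal_groups_give_zero_t_unit_p(self):
        expr = pd.DataFrame(
            [[1.0, 2.0, 3.0, 1.0, 2.0, 3.0], [5.0, 6.0, 9.0, 5.0, 6.0, 9.0]],
            index=["g1", "g2"],
            columns=[f"s{j}" for j in range(6)],
        )
        res = ttest_pipeline(expr, [f"s{j}" for j in range(3)],
                             [f"s{j}" for j in range(3, 6)])
        assert np.allclose(res["stat"], 0.0)
        assert np.allclose(res["pvalue"], 1.0)

    def test_swapping_groups_flips_sign(self):
        rng = np.random.default_rng(7)
        expr = pd.DataFrame(rng.normal(size=(30, 8)),
                            columns=[f"s{j}" for j in range(8)])
        a, b = [f"s{j}" for j in range(4)], [f"s{j}" for j in range(4, 8)]
        r1 = ttest_pipeline(expr, a, b)
        r2 = ttest_pipeline(expr, b, a)
        assert np.allclose(r1["stat"], -r2["stat"])
        assert np.allclose(r1["pvalue"], r2["pvalue"])

    def test_welch_closed_form(self):
        expr = pd.DataFrame([[1.0, 2.0, 3.0, 4.0, 5.0, 6.0]], index=["g"],
                            columns=[f"s{j}" for j in range(6)])
        res = ttest_pipeline(expr, ["s0", "s1", "s2"], ["s3", "s4", "s5"])
        # independent Welch evaluation
        a, b = np.array([1.0, 2.0, 3.0]), np.array([4.0, 5.0, 6.0])
        t_expect = (b.mean() - a.mean()) / np.sqrt(
            a.var(ddof=1) / 3 + b.var(ddof=1) / 3)
        assert np.isclose(res["stat"].iloc[0], t_expect)

    def test_constant_gene_excluded(self):
        expr = pd.DataFrame(
            [[2.0] * 6, [1, 2, 3, 4, 5, 6.0]],
            index=["flat", "ok"], columns=[f"s{j}" for j in range(6)],
        )
        res = ttest_pipeline(expr, [f"s{j}" for j in range(3)],
                             [f"s{j}" for j in range(3, 6)])
        assert np.isnan(res.loc["flat", "stat"])
        assert res["pvalue"].notna().sum() == 1


class TestBH:
    def test_hand_example(self):
        adj = bh_adjust([1e-4, 0.02, 0.03, 0.9])
        assert np.allclose(adj, [4e-4, 0.04, 0.04, 0.9])

    def test_monotone_in_rank_and_bounded(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(size=200)
        adj = bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)
        assert adj.max() <= 1.0
        assert np.all(adj >= p - 1e-15)

    def test_nan_excluded(self):
        adj = bh_adjust([0.01, np.nan, 0.04])
        assert np.isnan(adj[1])
        assert np.allclose(adj[[0, 2]], [0.02, 0.04])
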