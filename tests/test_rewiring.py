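import logging

import numpy as np
import pandas as pd
import pytest

from pancanmet.diffexp import CountMatrix, size_factors
from pancanmet.rewiring import (classify_rewiring, diversity, fold_vs_average,
                                normal_cancer_correlation, pathway_scores,
                                tissue_means, vst)
from pancanmet.signature import MetabolicSignature
from conftest import make_counts


def random_fixture(seed=0, n_genes=100, n_tissues=5, per_tissue=4):
    rng = np.random.default_rng(seed)
    samples, grouping = [], {}
    for t in range(n_tissues):
        for i in range(per_tissue):
            s = f"T{t}_s{i}"
            samples.append(s)
            grouping[s] = f"T{t}"
    counts = make_counts(rng, n_genes, samples)
    return CountMatrix(counts), grouping, rng


class TestVST:
    def test_monotone_in_counts(self):
        cm, _, _ = random_fixture(1)
        v = vst(cm)
        # per gene, VST order matches raw normalized-count order
        sf = size_factors(cm)
        q = cm.counts / sf
        for i in range(0, 40, 7):
            order_q = np.argsort(q.iloc[i].values)
            order_v = np.argsort(v.values.iloc[i].values)
            assert np.array_equal(order_q, order_v)

    def test_normalization_invariance_with_given_size_factors(self):
        cm, _, _ = random_fixture(2)
        sf = size_factors(cm)
        v1 = vst(cm, sf=sf)
        doubled = cm.counts.copy()
        doubled.iloc[:, 0] = doubled.iloc[:, 0] * 2
        sf2 = sf.copy()
        sf2.iloc[0] = sf2.iloc[0] * 2
        v2 = vst(CountMatrix(doubled), sf=sf2)
        s = cm.counts.columns[0]
        assert np.allclose(v1.values[s].values, v2.values[s].values, atol=1e-6)

    def test_sqrt_limit_for_small_dispersion(self):
        """With near-Poisson counts the fitted trend is tiny and the VST
        tracks 2*sqrt(normalized count)."""
        rng = np.random.default_rng(3)
        samples = [f"s{j}" for j in range(8)]
        mu = rng.uniform(5, 2000, 300)
        counts = pd.DataFrame(rng.poisson(mu[:, None], size=(300, 8)),
                              index=[f"g{i}" for i in range(300)],
                              columns=samples)
        cm = CountMatrix(counts)
        v = vst(cm)
        q = (cm.counts / size_factors(cm)).values.ravel()
        u = v.values.values.ravel()
        r = np.corrcoef(u, 2 * np.sqrt(q))[0, 1]
        assert r > 0.999

    def test_fallback_shifted_log(self, caplog):
        # 3 genes cannot support a trend fit -> fallback, tagged
        counts = pd.DataFrame([[10, 12], [20, 18], [5, 7]],
                              index=list("abc"), columns=["s1", "s2"])
        with caplog.at_level(logging.WARNING):
            v = vst(CountMatrix(counts))
        assert v.provenance == "shifted-log"
        assert any("FALLING BACK" in r.message for r in caplog.records)


class TestTissueMeans:
    def test_single_sample_per_tissue(self):
        cm, _, _ = random_fixture(4, per_tissue=1)
        v = vst(cm)
        grouping = {s: s.split("_")[0] for s in cm.samples}
        m = tissue_means(v, grouping)
        for s in cm.samples:
            assert np.allclose(m[s.split("_")[0]].values, v.values[s].values)

    def test_matches_loop_and_sample_order_invariance(self):
        cm, grouping, rng = random_fixture(5)
        v = vst(cm)
        m = tissue_means(v, grouping)
        for t in sorted(set(grouping.values())):
            cols = [s for s, tt in grouping.items() if tt == t]
            for i in range(0, 100, 13):
                expect = np.mean([v.values.loc[v.values.index[i], s] for s in cols])
                assert m.iloc[i][t] == pytest.approx(expect)
        shuffled_cols = list(rng.permutation(list(cm.samples)))
        v2 = type(v)(v.values[shuffled_cols], v.provenance)
        m2 = tissue_means(v2, grouping)
        pd.testing.assert_frame_equal(m, m2[m.columns])


class TestFoldVsAverage:
    def test_constant_gene_gives_unit_ratio(self):
        m = pd.DataFrame({"t1": [3.0, 2.0], "t2": [3.0, 4.0]}, index=["a", "b"])
        r = fold_vs_average(m)
        assert np.allclose(r.loc["a"], 1.0)

    def test_two_tissue_arithmetic(self):
        m = pd.DataFrame({"t1": [2.0], "t2": [4.0]}, index=["g"])
        r = fold_vs_average(m)
        assert np.allclose(r.loc["g"].values, [2 / 3, 4 / 3])

    def test_row_mean_identity(self):
        cm, grouping, _ = random_fixture(6)
        r = fold_vs_average(tissue_means(vst(cm), grouping))
        assert np.allclose(r.mean(axis=1).values, 1.0, atol=1e-12)

    def test_zero_average_flagged_nan(self, caplog):
        m = pd.DataFrame({"t1": [0.0, 1.0], "t2": [0.0, 3.0]}, index=["z", "g"])
        with caplog.at_level(logging.INFO):
            r = fold_vs_average(m)
        assert r.loc["z"].isna().all()
        assert r.loc["g"].notna().all()


class TestPathwayScores:
    def test_unit_r_gives_unit_score(self):
        r = pd.DataFrame(1.0, index=["a", "b"], columns=["t1", "t2"])
        sig = MetabolicSignature({"P": ("a", "b")})
        s = pathway_scores(r, sig)
        assert np.allclose(s.loc["P"].values, 1.0)

    def test_singleton_pathway(self):
        r = pd.DataFrame({"t1": [0.5, 2.0], "t2": [1.5, 1.0]}, index=["a", "b"])
        sig = MetabolicSignature({"P": ("b",)})
        s = pathway_scores(r, sig)
        assert np.allclose(s.loc["P"].values, r.loc["b"].values)

    def test_matches_nested_loop_oracle(self, random_signature):
        cm, grouping, _ = random_fixture(7, n_genes=120)
        r = fold_vs_average(tissue_means(vst(cm), grouping))
        r.index = [f"g{i:03d}" for i in range(120)]  # align with signature
        s = pathway_scores(r, random_signature)
        for name, genes in random_signature.pathways.items():
            for t in r.columns:
                vals = [r.loc[g, t] for g in genes if g in r.index]
                assert s.loc[name, t] == pytest.approx(np.mean(vals))

    def test_unmeasured_pathway_dropped(self, caplog):
        r = pd.DataFrame({"t1": [1.0]}, index=["a"])
        sig = MetabolicSignature({"P": ("a",), "GONE": ("zz",)})
        with caplog.at_level(logging.INFO):
            s = pathway_scores(r, sig)
        assert "GONE" not in s.index


class TestCorrelationAndDiversity:
    def scores(self, seed=8):
        rng = np.random.default_rng(seed)
        idx = [f"P{i}" for i in range(20)]
        N = pd.DataFrame(rng.normal(1, 0.2, size=(20, 3)), index=idx,
                         columns=["t1", "t2", "t3"])
        return N

    def test_identical_compartments_rho_one(self):
        N = self.scores()
        res = normal_cancer_correlation(N, N.copy(), {"t1": "t1", "t2": "t2"})
        assert np.allclose(res["rho"].values, 1.0)

    def test_rank_reversal_rho_minus_one(self):
        N = self.scores()
        C = -N
        res = normal_cancer_correlation(N, C, {"t1": "t1"})
        assert res["rho"].iloc[0] == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(9)
        idx = [f"P{i}" for i in range(15)]
        N = pd.DataFrame({"t": rng.integers(0, 5, 15).astype(float)}, index=idx)
        C = pd.DataFrame({"t": rng.integers(0, 5, 15).astype(float)}, index=idx)
        res = normal_cancer_correlation(N, C, {"t": "t"})
        rx = pd.Series(N["t"].values).rank().values  # midranks for ties
        ry = pd.Series(C["t"].values).rank().values
        expect = np.corrcoef(rx, ry)[0, 1]
        assert res["rho"].iloc[0] == pytest.approx(expect)

    def test_too_few_shared_pathways_skipped(self):
        N = self.scores().iloc[:3]
        res = normal_cancer_correlation(N, N.copy(), {"t1": "t1"})
        assert res.empty

    def test_diversity_examples(self):
        s = pd.DataFrame({"t1": [1.0, 1.0, 1.0], "t2": [0.0, 2.0, 1.0]})
        d = diversity(s)
        assert d["t1"] == 0.0
        two = diversity(pd.DataFrame({"t": [0.0, 2.0]}))
        assert two["t"] == pytest.approx(np.sqrt(2.0))


def enrich_frame(calls):
    df = pd.DataFrame({"significant": pd.Series(calls)})
    return df


class TestClassification:
    def test_rule_table(self):
        normal = {"T": enrich_frame({"P1": "upregulated", "P2": "upregulated",
                                     "P3": "downregulated", "P4": "ns"})}
        cancer = {"T": enrich_frame({"P1": "ns", "P2": "downregulated",
                                     "P3": "upregulated", "P4": "upregulated"})}
        res = classify_rewiring(normal, cancer)
        t = res["table"].set_index("pathway")
        assert t.loc["P1", "category"] == "maintained"
        assert t.loc["P2", "category"] == "lost"
        assert t.loc["P3", "category"] == "gained"
        assert t.loc["P4", "category"] == "unchanged"

    def test_fractions_partition_each_stratum(self):
        rng = np.random.default_rng(10)
        calls = ["upregulated", "downregulated", "ns"]
        normal, cancer = {}, {}
        for t in ["T1", "T2", "T3"]:
            normal[t] = enrich_frame(
                {f"P{i}": calls[rng.integers(3)] for i in range(30)})
            cancer[t] = enrich_frame(
                {f"P{i}": calls[rng.integers(3)] for i in range(30)})
        res = classify_rewiring(normal, cancer)
        sums = res["fractions"].groupby("normal_status")["fraction"].sum()
        assert np.allclose(sums.values, 1.0)

    def test_unmatched_tissues_error(self):
        normal = {"T1": enrich_frame({"P": "ns"})}
        cancer = {"T2": enrich_frame({"P": "ns"})}
        with pytest.raises(ValueError, match="different tissues"):
            classify_rewiring(normal, cancer)
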