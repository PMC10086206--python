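import numpy as np
import pandas as pd
import pytest

from epilnc import immune
from oracles import gsea_es_oracle, partial_corr_oracle, ssgsea_oracle


def series(values, ids=None):
    ids = ids or [f"g{i}" for i in range(len(values))]
    return pd.Series(values, index=ids, dtype=float)


class TestSsgsea:
    def test_top_ranked_set_is_maximal_and_positive(self):
        col = series([5, 4, 3, 2, 1, 0.5])
        top = immune.ssgsea(col, {"g0", "g1"})
        assert top > 0
        for other in ({"g2", "g3"}, {"g4", "g5"}, {"g0", "g5"}):
            assert immune.ssgsea(col, other) <= top

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        vals = rng.uniform(1, 10, 30)
        col = series(vals)
        gene_set = {f"g{i}" for i in rng.choice(30, 6, replace=False)}
        a = immune.ssgsea(col, gene_set)
        b = immune.ssgsea(series(np.exp(vals / 3)), gene_set)
        assert a == pytest.approx(b, abs=1e-12)

    def test_worked_example_matches_oracle(self):
        col = series([5, 4, 3, 2, 1], ["g1", "g2", "g3", "g4", "g5"])
        expected = ssgsea_oracle([5, 4, 3, 2, 1], ["g1", "g2", "g3", "g4", "g5"],
                                 {"g1", "g3"})
        assert immune.ssgsea(col, {"g1", "g3"}) == pytest.approx(expected, abs=1e-12)

    def test_degenerate_sets(self):
        col = series([3, 2, 1])
        with pytest.warns(UserWarning):
            assert np.isnan(immune.ssgsea(col, {"absent"}))
        with pytest.raises(ValueError):
            immune.ssgsea(col, {"g0", "g1", "g2"})


class TestSignatureScores:
    def test_duplicated_sample_gets_identical_row(self):
        rng = np.random.default_rng(2)
        expr = pd.DataFrame(rng.uniform(0, 8, (20, 3)),
                            index=[f"g{i}" for i in range(20)],
                            columns=["s1", "s2", "s3"])
        expr["s1_copy"] = expr["s1"]
        out = immune.signature_scores(expr, {"sig": {"g1", "g2", "g3"}})
        assert out.loc["s1", "sig"] == pytest.approx(out.loc["s1_copy", "sig"])

    def test_hot_subtype_has_higher_ifn_signature(self, small_cohort):
        from epilnc.er import wilcoxon_rank_sum
        scores = immune.signature_scores(
            small_cohort.expr, {"IFN": small_cohort.gene_sets["signatures"]["IFN_gamma_response"]}
        )
        hot = small_cohort.truth.subtype_labels == "Hot"
        s_hot = scores.loc[hot[hot].index, "IFN"]
        s_cold = scores.loc[hot[~hot].index, "IFN"]
        assert s_hot.mean() > s_cold.mean()
        _, p = wilcoxon_rank_sum(s_hot, s_cold)
        assert p < 0.01

    def test_single_gene_set_monotone_in_rank(self):
        expr = pd.DataFrame({"s1": [5, 1, 2], "s2": [1, 5, 2], "s3": [2, 1, 5]},
                            index=["gA", "gB", "gC"], dtype=float)
        out = immune.signature_scores(expr, {"solo": {"gA"}})
        assert out.loc["s1", "solo"] > out.loc["s3", "solo"] > out.loc["s2", "solo"]


class TestScalarScores:
    def test_cyt_geometric_mean(self):
        # linear values 4 and 9 (log2 of value+1), pseudocount 0 -> 6
        expr = pd.DataFrame({"s1": [np.log2(5.0), np.log2(10.0)]},
                            index=["GZMA", "PRF1"])
        assert immune.cyt_score(expr, pseudocount=0.0)["s1"] == pytest.approx(6.0)

    def test_cyt_equal_genes_and_zero_floor(self):
        expr = pd.DataFrame({"s1": [np.log2(8.0), np.log2(8.0)], "s2": [0.0, 0.0]},
                            index=["GZMA", "PRF1"])
        out = immune.cyt_score(expr, pseudocount=0.0)
        assert out["s1"] == pytest.approx(7.0)
        out2 = immune.cyt_score(expr, pseudocount=0.01)
        assert out2["s2"] == pytest.approx(0.01)

    def test_cyt_missing_gene_rejected(self):
        expr = pd.DataFrame({"s1": [1.0]}, index=["GZMA"])
        with pytest.raises(KeyError):
            immune.cyt_score(expr)

    def test_mhc_mean_expression(self):
        expr = pd.DataFrame({"s1": [2.0, 4.0, 6.0, 99.0]},
                            index=["a", "b", "c", "other"])
        assert immune.mhc_score(expr, {"a", "b", "c"})["s1"] == pytest.approx(4.0)
        assert immune.mhc_score(expr, {"a", "absent"})["s1"] == pytest.approx(2.0)
        with pytest.raises(ValueError):
            immune.mhc_score(expr, {"absent"})

    def test_estimate_like_components_swap_and_sum(self):
        rng = np.random.default_rng(3)
        expr = pd.DataFrame(rng.uniform(0, 8, (30, 4)),
                            index=[f"g{i}" for i in range(30)],
                            columns=[f"s{i}" for i in range(4)])
        s_set = {f"g{i}" for i in range(5)}
        i_set = {f"g{i}" for i in range(10, 15)}
        a = immune.estimate_like(expr, s_set, i_set)
        b = immune.estimate_like(expr, i_set, s_set)
        assert np.allclose(a["stromal"], b["immune"])
        assert np.allclose(a["combined"], a["stromal"] + a["immune"])


class TestDifferentialExpression:
    def test_group_swap_flips_logfc(self):
        rng = np.random.default_rng(4)
        expr = pd.DataFrame(rng.normal(5, 1, (10, 40)),
                            index=[f"g{i}" for i in range(10)],
                            columns=[f"s{i}" for i in range(40)])
        labels = pd.Series([1] * 20 + [2] * 20, index=expr.columns)
        flipped = labels.map({1: 2, 2: 1})
        de1 = immune.differential_expression(expr, labels)
        de2 = immune.differential_expression(expr, flipped)
        assert np.allclose(de1["logFC"], -de2["logFC"])
        assert np.allclose(de1["p"], de2["p"])

    def test_planted_logfc_detected(self):
        rng = np.random.default_rng(5)
        n_genes, shift_genes = 200, 50
        base = rng.normal(5, 1, (n_genes, 200))
        base[:shift_genes, :100] += 1.5
        expr = pd.DataFrame(base, index=[f"g{i}" for i in range(n_genes)],
                            columns=[f"s{i}" for i in range(200)])
        labels = pd.Series([1] * 100 + [2] * 100, index=expr.columns)
        de = immune.differential_expression(expr, labels)
        sens = de["flag"].iloc[:shift_genes].mean()
        fp = de["flag"].iloc[shift_genes:].mean()
        assert sens >= 0.95
        assert fp <= 0.05


class TestInfiltrationCorrelation:
    def _toy(self):
        rng = np.random.default_rng(6)
        n = 100
        driver = rng.normal(size=n)
        samples = [f"s{i}" for i in range(n)]
        expr = pd.DataFrame(
            {"coupled": 3 + driver + rng.normal(0, 0.5, n),
             "flat": rng.normal(3, 1, n),
             "same_sign": 3 + driver + rng.normal(0, 0.5, n)}).T
        expr.columns = samples
        meth = pd.DataFrame(
            {"coupled": 0.5 - 0.1 * driver + rng.normal(0, 0.05, n),
             "flat": rng.uniform(0.4, 0.6, n),
             "same_sign": 0.5 + 0.1 * driver + rng.normal(0, 0.05, n)}).T
        meth.columns = samples
        infil = pd.DataFrame({"CD8_T": 0.2 + 0.05 * driver + rng.normal(0, 0.01, n)},
                             index=samples)
        return expr, meth, infil

    def test_opposite_direction_rule(self):
        expr, meth, infil = self._toy()
        pairs, verdict = immune.infiltration_correlation(
            expr, meth, infil, ["coupled", "flat", "same_sign"]
        )
        by = pairs.set_index("lncrna")
        assert bool(by.loc["coupled", "passed"])
        assert not bool(by.loc["same_sign", "passed"])  # both r positive
        assert verdict.loc["coupled", "n_cells_passed"] == 1

    def test_too_few_samples_rejected(self):
        expr, meth, infil = self._toy()
        with pytest.raises(ValueError):
            immune.infiltration_correlation(expr.iloc[:, :2], meth.iloc[:, :2],
                                            infil.iloc[:2], ["coupled"])


class TestPartialCorrelation:
    def test_uncorrelated_control_reduces_to_pearson(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 6.0, 5.0])
        z = np.array([1.0, -1.0, -1.0, 1.0, -1.0, 1.0])  # orthogonal to both
        if abs(np.corrcoef(x, z)[0, 1]) < 1e-12 and abs(np.corrcoef(y, z)[0, 1]) < 1e-12:
            assert immune.partial_correlation(x, y, z) == pytest.approx(
                np.corrcoef(x, y)[0, 1]
            )

    def test_worked_example_matches_residual_oracle(self):
        x, y, z = [1, 2, 3, 4], [1, 3, 2, 4], [1, 1, 2, 2]
        assert immune.partial_correlation(x, y, z) == pytest.approx(
            partial_corr_oracle(x, y, z), abs=1e-10
        )

    def test_random_instances_match_residual_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            x, y, z = rng.normal(size=(3, 25))
            assert immune.partial_correlation(x, y, z) == pytest.approx(
                partial_corr_oracle(x, y, z), abs=1e-10
            )

    def test_collinear_control_rejected(self):
        x = np.arange(5.0)
        with pytest.raises(ValueError):
            immune.partial_correlation(x, x[::-1], 2 * x + 1)


class TestGseaES:
    def test_head_loaded_set_matches_oracle(self):
        ranked = [f"g{i}" for i in range(6)]
        weights = [0.9, 0.8, 0.3, 0.2, -0.4, -0.7]
        gene_set = {"g0", "g1"}
        es, running = immune.gsea_es(ranked, weights, gene_set)
        assert es == pytest.approx(gsea_es_oracle(ranked, weights, gene_set), abs=1e-12)
        assert es > 0.7

    def test_reversed_list_flips_sign_for_symmetric_weights(self):
        ranked = [f"g{i}" for i in range(8)]
        weights = [1.0] * 8
        gene_set = {"g0", "g1"}
        es_fwd, _ = immune.gsea_es(ranked, weights, gene_set)
        es_rev, _ = immune.gsea_es(ranked[::-1], weights[::-1], gene_set)
        assert es_fwd == pytest.approx(-es_rev, abs=1e-12)

    def test_interleaved_set_has_small_es(self):
        ranked = [f"g{i}" for i in range(10)]
        weights = [1.0] * 10
        gene_set = {"g1", "g3", "g5", "g7", "g9"}
        es, _ = immune.gsea_es(ranked, weights, gene_set)
        assert abs(es) <= 1 / 5 + 1e-12  # at most one unmatched step


class TestPathwayAssociation:
    def test_planted_link_detected(self, small_cohort):
        cohort = small_cohort
        lnc = sorted(cohort.truth.immune_lncrnas)[0]
        pcg_ids = [g for g in cohort.expr.index
                   if cohort.genes.loc[g, "biotype"] == "PCG"]
        est = cohort.gene_sets["estimate"]
        purity = immune.purity_from_estimate(
            immune.estimate_like(cohort.expr, est["STROMAL"], est["IMMUNE"])["combined"]
        )
        out = immune.lncrna_pathway_association(
            cohort.expr, lnc, cohort.gene_sets["pathways"], purity,
            pcg_ids=pcg_ids, n_perm=500, seed=3,
        ).set_index("pathway")
        immune_pw = [p for p in out.index if p.startswith("PW_IMMUNE")]
        null_pw = [p for p in out.index if p.startswith("PW_NULL")]
        assert (out.loc[immune_pw, "es"] > 0).all()
        # modest cohort (n=120): immune pathways positively enriched; the
        # uncoupled sets sit at or below the contaminated background, never above
        assert (out.loc[immune_pw, "fdr"] < 0.1).all()
        assert out.loc[null_pw, "es"].max() < out.loc[immune_pw, "es"].min()
        assert np.sign(out["nes"]).equals(np.sign(out["es"]))

    def test_zero_permutations_rejected(self, small_cohort):
        rng = np.random.default_rng(0)
        purity = pd.Series(rng.uniform(0.3, 0.9, small_cohort.expr.shape[1]),
                           index=small_cohort.expr.columns)
        with pytest.raises(ValueError):
            immune.lncrna_pathway_association(
                small_cohort.expr, "LNC0000", {}, purity, n_perm=0
            )
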