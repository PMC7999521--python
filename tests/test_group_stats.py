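import numpy as np
import pandas as pd
import pytest
from scipy import stats

from enterotyper import (
    AbundanceTable,
    EnterotypeLabels,
    PhenotypeTable,
    cooccurrence_matrix,
    kruskal_wallis,
    normalize_relative,
    per_feature_group_tests,
    phenotype_association_ranking,
    spearman,
)
from enterotyper.group_stats import benjamini_hochberg, compact_letters


class TestKruskalWallis:
    def test_textbook_three_group_value(self):
        values = np.arange(1, 10, dtype=float)
        groups = np.repeat([1, 2, 3], 3)
        h, p = kruskal_wallis(values, groups)
        assert h == pytest.approx(7.2, abs=1e-12)
        assert p == pytest.approx(stats.chi2.sf(7.2, 2), abs=1e-12)

    def test_identical_values_give_null_result(self):
        h, p = kruskal_wallis(np.ones(9), np.repeat([1, 2, 3], 3))
        assert (h, p) == (0.0, 1.0)

    def test_two_groups_equal_squared_standardized_rank_sum(self):
        # Wilcoxon equivalence: H = (W - E[W])^2 / Var[W] for two tie-free groups
        rng = np.random.default_rng(0)
        values = rng.permutation(20).astype(float) + 1
        groups = np.repeat([1, 2], 10)
        h, _ = kruskal_wallis(values, groups)
        n1, n2, n = 10, 10, 20
        w = stats.rankdata(values)[groups == 1].sum()
        z2 = (w - n1 * (n + 1) / 2) ** 2 / (n1 * n2 * (n + 1) / 12)
        assert h == pytest.approx(z2, abs=1e-10)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        values = rng.normal(size=15)
        groups = np.repeat([1, 2, 3], 5)
        h1, p1 = kruskal_wallis(values, groups)
        h2, p2 = kruskal_wallis(np.exp(values * 3), groups)
        assert h1 == pytest.approx(h2, abs=1e-10)
        assert p1 == pytest.approx(p2, abs=1e-10)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="2 groups"):
            kruskal_wallis(np.arange(5.0), np.ones(5))


class TestSpearman:
    def test_strictly_monotone_gives_one(self):
        rho, _ = spearman([1.0, 2.0, 5.0, 9.0], [0.1, 0.7, 0.9, 4.0])
        assert rho == pytest.approx(1.0, abs=1e-12)

    def test_textbook_negative_half(self):
        rho, _ = spearman([1, 2, 3], [3, 1, 2])
        assert rho == pytest.approx(-0.5, abs=1e-12)

    def test_ties_equal_pearson_on_midranks(self):
        rng = np.random.default_rng(2)
        x = rng.integers(0, 5, size=30).astype(float)  # heavy ties
        y = rng.integers(0, 5, size=30).astype(float)
        rho, _ = spearman(x, y)
        oracle = stats.pearsonr(stats.rankdata(x), stats.rankdata(y)).statistic
        assert rho == pytest.approx(oracle, abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=20), rng.normal(size=20)
        r1, _ = spearman(x, y)
        r2, _ = spearman(np.exp(x), y**3)
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="rank variance"):
            spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestBenjaminiHochberg:
    def test_monotone_and_bounded(self):
        p = np.array([0.001, 0.02, 0.03, 0.5, 0.8])
        q = benjamini_hochberg(p)
        assert (q >= p - 1e-15).all() and (q <= 1.0).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_single_test_unchanged(self):
        assert benjamini_hochberg([0.03])[0] == pytest.approx(0.03)


class TestCompactLetters:
    def test_no_differences_single_letter(self):
        assert compact_letters(3, []) == ["a", "a", "a"]

    def test_one_group_distinct(self):
        assert compact_letters(3, [(0, 2), (1, 2)]) == ["a", "a", "b"]

    def test_all_pairwise_distinct(self):
        assert compact_letters(3, [(0, 1), (0, 2), (1, 2)]) == ["a", "b", "c"]

    def test_chain_shares_middle_group(self):
        # 0 != 2 but 1 indistinguishable from both
        letters = compact_letters(3, [(0, 2)])
        assert letters[0] != letters[2]
        assert set(letters[1]) & set(letters[0])
        assert set(letters[1]) & set(letters[2])


def _labels(groups):
    return EnterotypeLabels([f"s{i}" for i in range(len(groups))], np.asarray(groups))


class TestPerFeatureGroupTests:
    def _frame(self, cols, n_per=10, k=3):
        idx = [f"s{i}" for i in range(n_per * k)]
        return pd.DataFrame(cols, index=idx)

    def test_planted_effect_in_one_group_detected(self):
        rng = np.random.default_rng(4)
        groups = np.repeat([1, 2, 3], 12)
        flat = rng.normal(0, 1, size=36)
        shifted = rng.normal(0, 1, size=36) + np.where(groups == 3, 6.0, 0.0)
        df = self._frame({"null_feat": flat, "hit_feat": shifted}, n_per=12)
        out = per_feature_group_tests(df, _labels(groups))
        assert out.loc["hit_feat", "p_value"] < 0.001
        assert out.loc["hit_feat", "letter_ET1"] == out.loc["hit_feat", "letter_ET2"]
        assert out.loc["hit_feat", "letter_ET3"] != out.loc["hit_feat", "letter_ET1"]

    def test_constant_feature_yields_p_one_shared_letter(self):
        groups = np.repeat([1, 2, 3], 5)
        df = self._frame({"const": np.ones(15)}, n_per=5)
        out = per_feature_group_tests(df, _labels(groups))
        assert out.loc["const", "p_value"] == 1.0
        assert out.loc["const", "H_statistic"] == 0.0
        assert (
            out.loc["const", "letter_ET1"]
            == out.loc["const", "letter_ET2"]
            == out.loc["const", "letter_ET3"]
            == "a"
        )

    def test_single_feature_q_equals_p(self):
        rng = np.random.default_rng(5)
        groups = np.repeat([1, 2], 8)
        df = self._frame({"only": rng.normal(size=16)}, n_per=8, k=2)
        out = per_feature_group_tests(df, _labels(groups))
        assert out["q_value"].iloc[0] == pytest.approx(out["p_value"].iloc[0])

    def test_tiny_group_skipped_with_warning(self):
        groups = np.array([1, 1, 1, 2, 2, 2, 3])  # group 3 has one sample
        df = pd.DataFrame({"f": np.arange(7.0)}, index=[f"s{i}" for i in range(7)])
        with pytest.warns(UserWarning, match="skipped"):
            out = per_feature_group_tests(df, _labels(groups))
        assert len(out) == 0

    def test_group_means_match_direct_computation(self):
        groups = np.repeat([1, 2], 6)
        vals = np.arange(12.0)
        df = pd.DataFrame({"f": vals}, index=[f"s{i}" for i in range(12)])
        out = per_feature_group_tests(df, _labels(groups))
        assert out.loc["f", "mean_ET1"] == pytest.approx(vals[:6].mean())
        assert out.loc["f", "sem_ET2"] == pytest.approx(
            vals[6:].std(ddof=1) / np.sqrt(6)
        )


class TestCooccurrence:
    def test_unit_diagonal_and_symmetry(self, default_cohort):
        table, _, _ = default_cohort
        res = cooccurrence_matrix(normalize_relative(table), top_n=8)
        np.testing.assert_allclose(np.diag(res.rho.to_numpy()), 1.0)
        np.testing.assert_allclose(res.rho.to_numpy(), res.rho.to_numpy().T, atol=1e-15)

    def test_comonotone_taxa_correlate_perfectly(self):
        base = np.linspace(1, 2, 10)
        df = pd.DataFrame(
            {"a": base, "b": 2 * base, "c": 10 - base},
            index=[f"s{i}" for i in range(10)],
        )
        table = normalize_relative(AbundanceTable(df, "counts"))
        res = cooccurrence_matrix(table, top_n=3)
        assert res.rho.loc["c", "a"] == pytest.approx(-1.0)  # after closure a,b flip
        assert res.rho.loc["a", "b"] == pytest.approx(1.0)

    def test_planted_trio_cooccurs_and_cross_drivers_anticorrelate(self, default_cohort):
        table, _, _ = default_cohort
        res = cooccurrence_matrix(normalize_relative(table), top_n=12)
        trio = ["Clostridium sensu stricto 1", "Turicibacter", "Romboutsia"]
        for i, a in enumerate(trio):
            for b in trio[i + 1 :]:
                assert res.rho.loc[a, b] > 0.6
        assert res.rho.loc["Clostridium sensu stricto 1", "Bacteroides"] < 0
        assert res.rho.loc["Bifidobacterium", "Bacteroides"] < 0
        assert res.rho.loc["Lactobacillus", "Bifidobacterium"] < 0

    def test_constant_taxon_flagged_not_dropped(self):
        df = pd.DataFrame(
            {"a": [1.0, 2.0, 3.0, 4.0], "b": [4.0, 3.0, 2.0, 1.0], "c": [1.0] * 4},
            index=[f"s{i}" for i in range(4)],
        )
        table = AbundanceTable(df, "counts")
        res = cooccurrence_matrix(table, top_n=3)
        flagged = res.long[res.long["undefined"]]
        assert len(flagged) == 2
        assert np.isnan(res.rho.loc["c", "a"])

    def test_top_n_limit_enforced(self, toy_counts):
        with pytest.raises(ValueError, match="exceeds"):
            cooccurrence_matrix(normalize_relative(toy_counts), top_n=99)


class TestAssociationRanking:
    def test_planted_top_producer_ranks_first(self, default_cohort):
        table, phen, _ = default_cohort
        res = phenotype_association_ranking(
            normalize_relative(table), phen, ["Faecalibacterium", "Butyricicoccus", "Blautia"]
        )
        assert res.table.index[0] == "Faecalibacterium"
        assert res.table["rho_butyrate"].is_monotonic_decreasing

    def test_absent_candidate_reported_not_fatal(self, default_cohort):
        table, phen, _ = default_cohort
        res = phenotype_association_ranking(
            normalize_relative(table), phen, ["Faecalibacterium", "NotARealGenus"]
        )
        assert res.skipped_taxa == ["NotARealGenus"]
        assert "Faecalibacterium" in res.table.index

    def test_noise_free_monotone_coupling_gives_rho_one(self):
        n = 12
        x = np.linspace(0.01, 0.2, n)
        df = pd.DataFrame({"prod": x, "other": 1 - x}, index=[f"s{i}" for i in range(n)])
        table = AbundanceTable(df.div(df.sum(axis=1), axis=0), "relative")
        phen = PhenotypeTable(
            pd.DataFrame(
                {
                    "butyrate_mg_per_g": 3 * x + 0.5,
                    "buk_log10_copies": np.log10(1e7 * (1 + x)),
                    "but_log10_copies": np.log10(1e8 * (1 + 2 * x)),
                },
                index=df.index,
            )
        )
        res = phenotype_association_ranking(table, phen, ["prod"])
        assert res.table.loc["prod", "rho_butyrate"] == pytest.approx(1.0)
        assert res.gene_correlations["but"]["rho"] == pytest.approx(1.0)

    def test_too_few_samples_rejected(self):
        df = pd.DataFrame({"a": [1.0, 2.0]}, index=["s1", "s2"])
        table = AbundanceTable(df.div(df.sum(axis=1), axis=0), "relative")
        phen = PhenotypeTable(
            pd.DataFrame(
                {
                    "butyrate_mg_per_g": [1.0, 2.0],
                    "buk_log10_copies": [7.0, 7.1],
                    "but_log10_copies": [8.0, 8.1],
                },
                index=["s1", "s2"],
            )
        )
        with pytest.raises(ValueError, match="fewer than 3"):
            phenotype_association_ranking(table, phen, ["a"])
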