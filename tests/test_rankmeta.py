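"""Rank-product meta-analysis: ranking, null p-values, BH, Fisher, pipeline."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from resistrank.diffexp import ComparisonResult
from resistrank.io import GeneSet
from resistrank.rankmeta import (
    MetaConfig,
    RankTable,
    bh_adjust,
    filter_and_rank_metabolic,
    fisher_combine,
    rank_by_lfc,
    rank_product,
    rp_pvalue_exact,
    rp_pvalue_gamma,
    rp_pvalue_permutation,
    run_meta,
    storey_qvalues,
)
from resistrank.simulate import SimConfig, simulate_cohorts


def comparison_from_lfc(lfc: dict[str, float], cid: str = "c1") -> ComparisonResult:
    table = pd.DataFrame({"log2fc": pd.Series(lfc)})
    return ComparisonResult(comparison_id=cid, study_id=cid, table=table)


class TestRanking:
    def test_descending_fold_change_order(self):
        rt = rank_by_lfc(comparison_from_lfc({"a": 3.0, "b": 1.0, "c": 2.0}))
        assert rt.ranks.tolist() == [1.0, 3.0, 2.0]

    def test_ties_get_average_ranks(self):
        rt = rank_by_lfc(comparison_from_lfc({"a": 5.0, "b": 5.0, "c": 1.0, "d": 0.0}))
        assert rt.ranks["a"] == rt.ranks["b"] == 1.5

    def test_label_reversal_reverses_ranks(self):
        lfc = {"a": 3.0, "b": 1.0, "c": -2.0, "d": 0.5}
        fwd = rank_by_lfc(comparison_from_lfc(lfc)).ranks
        rev = rank_by_lfc(comparison_from_lfc({g: -v for g, v in lfc.items()})).ranks
        assert np.allclose(rev, len(lfc) + 1 - fwd)

    def test_empty_comparison_rejected(self):
        with pytest.raises(ValueError):
            rank_by_lfc(comparison_from_lfc({}))


class TestRankProduct:
    def test_single_study_identity(self):
        rt = rank_by_lfc(comparison_from_lfc({"a": 3.0, "b": 1.0, "c": 2.0}))
        out = rank_product([rt])
        assert np.allclose(out["rho"], rt.ranks / 3)

    def test_best_possible_product(self):
        tables = [
            RankTable(f"c{i}", pd.Series(np.arange(1, 1322.0), index=range(1321)), 1321)
            for i in range(4)
        ]
        out = rank_product(tables)
        assert out.loc[0, "raw_product"] == 1.0
        assert out.loc[0, "rho"] == pytest.approx(1 / 1321)

    def test_relative_geometric_mean_arithmetic(self):
        t1 = RankTable("c1", pd.Series([2.0, 1.0, 3.0, 4.0], index=list("abcd")), 4)
        t2 = RankTable("c2", pd.Series([3.0, 1.0, 2.0, 4.0], index=list("abcd")), 4)
        out = rank_product([t1, t2])
        assert out.loc["a", "raw_product"] == 6.0
        assert out.loc["a", "rho"] == pytest.approx(math.sqrt(6 / 16), abs=1e-4)

    def test_min_studies_controls_gene_inclusion(self):
        t1 = RankTable("c1", pd.Series([1.0, 2.0], index=["a", "b"]), 2)
        t2 = RankTable("c2", pd.Series([1.0, 2.0], index=["a", "c"]), 2)
        assert set(rank_product([t1, t2], min_studies=1).index) == {"a", "b", "c"}
        assert set(rank_product([t1, t2], min_studies=2).index) == {"a"}
        with pytest.raises(ValueError):
            rank_product([RankTable("c1", pd.Series([1.0], index=["a"]), 1),
                          RankTable("c2", pd.Series([1.0], index=["b"]), 1)], min_studies=2)


class TestExactPValue:
    def test_single_study_uniform_tail(self):
        assert rp_pvalue_exact(3, [10]) == pytest.approx(0.3)

    def test_two_study_enumeration(self):
        assert rp_pvalue_exact(2, [4, 4]) == pytest.approx(3 / 16)

    def test_maximal_statistic_gives_one(self):
        assert rp_pvalue_exact(4 * 4 * 4, [4, 4, 4]) == pytest.approx(1.0)

    def test_agrees_with_brute_force_enumeration(self):
        sizes = [5, 7, 6]
        for product in (1, 10, 40, 100, 210):
            brute = sum(
                1
                for tup in itertools.product(*(range(1, n + 1) for n in sizes))
                if math.prod(tup) <= product
            ) / math.prod(sizes)
            assert rp_pvalue_exact(product, sizes) == pytest.approx(brute)

    def test_budget_guard(self):
        with pytest.raises(ValueError, match="budget"):
            rp_pvalue_exact(10, [1000, 1000, 1000], budget=10_000)


class TestGammaPValue:
    def test_worst_rank_is_near_one(self):
        assert rp_pvalue_gamma([10], [10]) > 0.99

    def test_best_ranks_in_four_large_studies_are_vanishing(self):
        p = rp_pvalue_gamma([1, 1, 1, 1], [1321] * 4)
        assert 0 < p < 1e-10
        # within an order of magnitude of the exact 1/1321^4 tail
        exact = 1.0 / 1321**4
        assert exact / 10 < p < exact * 10

    def test_exhaustive_agreement_with_enumeration_oracle(self):
        # every rank tuple for k = 3 studies of 8 genes: max |gamma - exact| <= 0.02
        sizes = [8, 8, 8]
        worst = 0.0
        for tup in itertools.product(*(range(1, n + 1) for n in sizes)):
            exact = rp_pvalue_exact(math.prod(tup), sizes)
            approx = rp_pvalue_gamma(list(tup), sizes)
            worst = max(worst, abs(exact - approx))
        assert worst <= 0.02

    def test_monotone_in_rank_product(self):
        sizes = [50, 50]
        p_prev = 0.0
        for r in range(1, 51):
            p = rp_pvalue_gamma([r, r], sizes)
            assert p >= p_prev
            p_prev = p

    def test_out_of_range_ranks_rejected(self):
        with pytest.raises(ValueError):
            rp_pvalue_gamma([0], [10])
        with pytest.raises(ValueError):
            rp_pvalue_gamma([11], [10])


class TestPermutationPValue:
    def test_maximal_statistic(self):
        p, _ = rp_pvalue_permutation(1.0, [10, 10], n_permutations=2000, seed=0)
        assert p == pytest.approx(1.0, abs=1 / 2001)

    def test_agrees_with_exact_oracle(self):
        sizes = [6, 6]
        raw = 8
        exact = rp_pvalue_exact(raw, sizes)
        rho = math.sqrt(raw / 36)
        p, se = rp_pvalue_permutation(rho, sizes, n_permutations=100_000, seed=1)
        assert abs(p - exact) < 3 * se

    def test_seeded_determinism_and_min_permutations(self):
        a = rp_pvalue_permutation(0.3, [20, 20], n_permutations=5000, seed=7)
        b = rp_pvalue_permutation(0.3, [20, 20], n_permutations=5000, seed=7)
        assert a == b
        with pytest.raises(ValueError):
            rp_pvalue_permutation(0.3, [20, 20], n_permutations=10)


class TestBHAdjust:
    def test_hand_worked_step_up(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])

    def test_exchangeable_and_singleton_cases(self):
        assert np.allclose(bh_adjust([0.2, 0.2, 0.2]), 0.2)
        assert bh_adjust([0.07])[0] == pytest.approx(0.07)

    def test_matches_statsmodels_reference(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(0)
        p = rng.uniform(1e-6, 1.0, size=500)
        assert np.allclose(bh_adjust(p), multipletests(p, method="fdr_bh")[1])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=1e-9, max_value=1.0), min_size=1, max_size=50),
           st.randoms(use_true_random=False))
    def test_invariant_to_input_order(self, p, rnd):
        arr = np.array(p)
        perm = np.array(rnd.sample(range(arr.size), arr.size))
        direct = bh_adjust(arr)
        permuted = bh_adjust(arr[perm])
        assert np.allclose(direct[perm], permuted)

    def test_rejects_out_of_range(self):
        for bad in ([0.0, 0.5], [0.5, 1.2], [np.nan]):
            with pytest.raises(ValueError):
                bh_adjust(bad)

    def test_storey_q_no_larger_than_bh(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(1e-6, 1.0, size=400)
        assert np.all(storey_qvalues(p) <= bh_adjust(p) + 1e-12)


class TestFisherCombine:
    def test_single_study_identity(self):
        x, df, p = fisher_combine([0.037])
        assert df == 2
        assert p == pytest.approx(0.037, rel=1e-12)

    def test_four_study_hand_calculation(self):
        x, df, p = fisher_combine([0.05] * 4)
        assert x == pytest.approx(23.966, abs=1e-3)
        assert df == 8
        assert p == pytest.approx(0.00233, abs=2e-5)
        assert p == pytest.approx(float(stats.chi2.sf(x, 8)), rel=1e-12)

    def test_p_of_one_contributes_nothing(self):
        x_with, _, _ = fisher_combine([0.1, 1.0])
        x_without, _, _ = fisher_combine([0.1])
        assert x_with == pytest.approx(x_without)

    def test_zero_p_is_floored_not_fatal(self):
        x, df, p = fisher_combine([0.0, 0.5])
        assert math.isfinite(x) and p > 0

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=1e-9, max_value=1.0), min_size=2, max_size=8))
    def test_exchangeable_in_arguments(self, p):
        assert fisher_combine(p) == pytest.approx(fisher_combine(p[::-1]))


class TestMetabolicFilter:
    @staticmethod
    def toy_meta() -> pd.DataFrame:
        return pd.DataFrame(
            {"rho": [0.1, 0.5, 0.3, 0.9], "p_rp": [0.01, 0.5, 0.2, 0.99]},
            index=["a", "b", "c", "d"],
        )

    def test_full_universe_filter_is_identity_up_to_ranking(self):
        meta = self.toy_meta()
        out = filter_and_rank_metabolic(meta, GeneSet.from_iterable("all", meta.index))
        assert set(out.index) == set(meta.index)
        assert out["meta_rank"].tolist() == [1, 2, 3, 4]
        assert out.index.tolist() == ["a", "c", "b", "d"]

    def test_restriction_and_order_preservation(self):
        out = filter_and_rank_metabolic(self.toy_meta(), GeneSet.from_iterable("m", ["b", "c"]))
        assert out.index.tolist() == ["c", "b"]
        assert out["meta_rank"].tolist() == [1, 2]

    def test_meta_rank_is_a_permutation_even_with_ties(self):
        meta = pd.DataFrame({"rho": [0.2, 0.2, 0.2], "p_rp": [0.1, 0.1, 0.1]},
                            index=["x", "y", "z"])
        out = filter_and_rank_metabolic(meta, GeneSet.from_iterable("m", ["x", "y", "z"]))
        assert sorted(out["meta_rank"]) == [1, 2, 3]

    def test_empty_intersection_rejected(self):
        with pytest.raises(ValueError):
            filter_and_rank_metabolic(self.toy_meta(), GeneSet.from_iterable("m", ["zz"]))


class TestRunMeta:
    def test_single_comparison_rejected(self):
        cfg = SimConfig(n_genes=50, n_studies=1, seed=0)
        studies, _ = simulate_cohorts(cfg)
        with pytest.raises(ValueError):
            run_meta(studies)

    def test_spiked_gene_wins_and_manifest_records_run(self):
        cfg = SimConfig(n_genes=300, n_studies=4, spikes={"gene_001": 3.0}, seed=5)
        studies, truth = simulate_cohorts(cfg)
        result, manifest = run_meta(studies, metabolic=truth.metabolic_genes)
        # spiked gene is metabolic by construction and should head the ranking
        assert result.index[0] == "gene_001"
        assert result.iloc[0]["meta_rank"] == 1
        assert result.iloc[0]["p_adj"] < result["p_adj"].median()
        assert manifest["n_comparisons"] == 4
        assert len(manifest["config_sha256"]) == 64

    def test_adjusted_p_dominates_raw_p(self):
        cfg = SimConfig(n_genes=200, n_studies=3, seed=6)
        studies, _ = simulate_cohorts(cfg)
        result, _ = run_meta(studies)
        assert np.all(result["p_adj"] >= result["p_rp"] - 1e-15)
        assert np.all((result["rho"] > 0) & (result["rho"] <= 1))
        assert sorted(result["meta_rank"]) == list(range(1, 201))

    def test_null_runs_rarely_reach_significance(self):
        # no spikes: the smallest BH-adjusted rank-product p should exceed
        # 0.05 in the vast majority of runs
        hits = 0
        for seed in range(100):
            cfg = SimConfig(n_genes=500, n_studies=4, n_responders=5,
                            n_nonresponders=5, seed=seed)
            studies, _ = simulate_cohorts(cfg)
            result, _ = run_meta(studies)
            if result["p_adj"].min() <= 0.05:
                hits += 1
        assert hits <= 5

    def test_permutation_and_gamma_methods_agree_on_the_top_gene(self):
        cfg = SimConfig(n_genes=100, n_studies=3, spikes={"gene_001": 3.0}, seed=8)
        studies, _ = simulate_cohorts(cfg)
        r_gamma, _ = run_meta(studies, config=MetaConfig(p_method="gamma"))
        r_perm, _ = run_meta(
            studies, config=MetaConfig(p_method="perm", n_permutations=20_000, seed=9)
        )
        assert r_gamma.index[0] == r_perm.index[0] == "gene_001"
        se = math.sqrt(r_perm["p_rp"].iloc[0] * (1 - r_perm["p_rp"].iloc[0]) / 20_000)
        assert abs(r_gamma["p_rp"].iloc[0] - r_perm["p_rp"].iloc[0]) <= max(3 * se, 5e-4)

    def test_exact_method_on_a_tiny_problem(self):
        cfg = SimConfig(n_genes=12, n_studies=2, spikes={"gene_01": 3.0}, noise_sd=0.1, seed=10)
        studies, _ = simulate_cohorts(cfg)
        result, _ = run_meta(studies, config=MetaConfig(p_method="exact"))
        top = result.iloc[0]
        assert top["p_rp"] == pytest.approx(
            rp_pvalue_exact(top["raw_product"], [12, 12]), rel=1e-12
        )
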