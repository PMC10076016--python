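"""Environment-association tests: Pearson p-values, harmonic-mean combination,
gene ranking, and the variant-count-matched permutation test."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from mozevo.association import (
    UndefinedCorrelation,
    associate_genes,
    gene_metric,
    harmonic_mean_p,
    hmp_adjusted,
    pearson_with_p,
    permutation_pvalue,
    rank_genes,
)


class TestPearsonWithP:
    def test_perfect_correlation(self):
        x = np.arange(10.0)
        r, p, n = pearson_with_p(x, x)
        assert r == 1.0 and p < 1e-200 and n == 10

    def test_antisymmetry(self):
        x = np.arange(10.0)
        r, _, _ = pearson_with_p(x, -x)
        assert r == -1.0

    def test_matches_scipy_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for n in (4, 7, 30):
            for _ in range(20):
                x, y = rng.standard_normal(n), rng.standard_normal(n)
                r, p, _ = pearson_with_p(x, y)
                sr, sp = stats.pearsonr(x, y)
                assert r == pytest.approx(sr, abs=1e-12)
                assert p == pytest.approx(sp, rel=1e-9)

    def test_pairwise_deletion_of_missing(self):
        x = np.array([1.0, 2.0, np.nan, 4.0, 5.0])
        y = np.array([2.0, 4.0, 6.0, np.nan, 10.0])
        r, _, n = pearson_with_p(x, y)
        assert n == 3 and r == pytest.approx(1.0)

    def test_constant_vector_undefined(self):
        with pytest.raises(UndefinedCorrelation):
            pearson_with_p([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])

    def test_too_few_pairs_undefined(self):
        with pytest.raises(UndefinedCorrelation):
            pearson_with_p([1.0, 2.0], [3.0, 1.0])

    def test_p_uniform_under_exhaustive_permutation_n4(self):
        """Permutation p-values of |r| over all 24 orderings are uniform on
        their achievable values (exchangeability sanity check)."""
        from itertools import permutations

        x = np.array([0.0, 1.0, 2.0, 4.0])
        y0 = np.array([3.0, 1.0, 4.0, 2.0])
        rs = []
        for perm in permutations(range(4)):
            r, _, _ = pearson_with_p(x, y0[list(perm)])
            rs.append(abs(r))
        rs = np.array(rs)
        perm_ps = np.array([(rs >= r - 1e-12).mean() for r in rs])
        # each achievable level is hit by the right fraction of orderings
        for level in np.unique(perm_ps):
            assert ((perm_ps <= level + 1e-12).mean()
                    == pytest.approx(level, abs=1e-12))


class TestHarmonicMeanP:
    def test_equal_inputs_return_that_p(self):
        assert harmonic_mean_p([0.2] * 7) == pytest.approx(0.2)

    def test_two_value_worked_example(self):
        assert harmonic_mean_p([0.01, 0.04]) == pytest.approx(2 / 125, abs=1e-15)

    def test_single_p_returned(self):
        assert harmonic_mean_p([0.37]) == pytest.approx(0.37)

    def test_zero_p_clamped_with_warning(self):
        with pytest.warns(UserWarning):
            p = harmonic_mean_p([0.0, 0.5])
        assert p > 0

    def test_empty_list_errors(self):
        with pytest.raises(ValueError):
            harmonic_mean_p([])

    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=20))
    def test_between_min_and_max_for_equal_weights(self, ps):
        h = harmonic_mean_p(ps)
        assert min(ps) - 1e-12 <= h <= max(ps) + 1e-12

    def test_adjusted_equals_raw_for_single_p(self):
        assert hmp_adjusted([0.123]) == pytest.approx(0.123)

    def test_adjusted_is_larger_than_raw_for_multiple_tests(self):
        ps = [0.001, 0.2, 0.5, 0.9]
        assert hmp_adjusted(ps) > harmonic_mean_p(ps)


class TestGeneMetric:
    def test_single_variant_log(self):
        a = gene_metric("g", "v", [0.01])
        assert a.metric == pytest.approx(2.0) and a.L == 1

    def test_combined_p_one_gives_zero_metric(self):
        a = gene_metric("g", "v", [1.0, 1.0])
        assert a.metric == pytest.approx(0.0)

    def test_five_variant_hand_computation(self):
        ps = [0.5, 0.2, 0.01, 0.8, 0.05]
        raw = 1.0 / (sum(1.0 / p for p in ps) / len(ps))
        a = gene_metric("g", "v", ps)
        assert a.combined_p == pytest.approx(raw, rel=1e-12)
        assert a.metric == pytest.approx(-math.log10(raw), rel=1e-12)

    def test_metric_invariant_to_variant_order(self):
        ps = [0.5, 0.2, 0.01, 0.8, 0.05]
        assert gene_metric("g", "v", ps).metric == pytest.approx(
            gene_metric("g", "v", ps[::-1]).metric
        )


class TestRankGenes:
    def _metrics(self, values):
        return pd.DataFrame({"var1": values}, index=[f"g{i}" for i in range(len(values))])

    def test_strict_maximum_flagged(self):
        m = self._metrics(list(np.linspace(0, 1, 50)) + [10.0])
        pct, flags = rank_genes(m)
        assert flags.loc["g50", "var1"]

    def test_identical_metrics_none_flagged(self):
        pct, flags = rank_genes(self._metrics([1.0] * 10))
        assert (pct["var1"] == 50.0).all() and not flags["var1"].any()

    def test_fewer_than_two_genes_errors(self):
        with pytest.raises(ValueError):
            rank_genes(self._metrics([1.0]))


class TestPermutationPvalue:
    def test_extreme_observation_gives_minimal_p(self):
        pool = np.linspace(0, 1, 100)
        obs = np.array([5.0, 5.0])
        B = 99
        assert permutation_pvalue(obs, pool, B, seed=1) == pytest.approx(1 / (B + 1))

    def test_gene_equal_to_pool_gives_p_one(self):
        pool = np.linspace(0, 1, 10)
        assert permutation_pvalue(pool, pool, 50, seed=1) == 1.0

    def test_reproducible_given_seed(self):
        rng = np.random.default_rng(3)
        pool = rng.random(200)
        obs = pool[:10]
        p1 = permutation_pvalue(obs, pool, 200, seed=11)
        p2 = permutation_pvalue(obs, pool, 200, seed=11)
        assert p1 == p2

    def test_pool_smaller_than_gene_errors(self):
        with pytest.raises(ValueError):
            permutation_pvalue(np.ones(5), np.ones(3), 10, seed=1)

    def test_zero_permutations_errors(self):
        with pytest.raises(ValueError):
            permutation_pvalue(np.ones(2), np.ones(5), 0, seed=1)


class TestAssociateGenes:
    @staticmethod
    def _variant_corr():
        rng = np.random.default_rng(8)
        rows = []
        for g in range(6):
            for v in range(5):
                rows.append(
                    (f"g{g}:v{v}", "var1", float(rng.uniform(-1, 1)),
                     float(rng.uniform(0.001, 1)), 20)
                )
        return pd.DataFrame(rows, columns=["variant_id", "variable", "r", "p", "n_used"])

    def test_table_shape_and_percentiles(self):
        vc = self._variant_corr()
        mapping = {vid: vid.split(":")[0] for vid in vc["variant_id"]}
        df = associate_genes(vc, mapping)
        assert len(df) == 6 and df["L"].eq(5).all()
        assert df["percentile"].between(0, 100).all()

    def test_permutation_requires_seed(self):
        vc = self._variant_corr()
        mapping = {vid: vid.split(":")[0] for vid in vc["variant_id"]}
        with pytest.raises(ValueError):
            associate_genes(vc, mapping, B=10, seed=None)

    def test_bit_exact_reproducibility_with_seed(self):
        vc = self._variant_corr()
        mapping = {vid: vid.split(":")[0] for vid in vc["variant_id"]}
        a = associate_genes(vc, mapping, B=50, seed=5)
        b = associate_genes(vc, mapping, B=50, seed=5)
        pd.testing.assert_frame_equal(a, b)
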