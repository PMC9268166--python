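import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lipochemo import srd
from lipochemo.synthetic import make_lipo_table


class TestRanking:
    @pytest.mark.parametrize(
        "values, expected",
        [
            ((0.1, 0.5, 0.9), (1, 2, 3)),
            ((5, 5, 1), (2.5, 2.5, 1)),
            ((3, 1, 2, 2), (4, 1, 2.5, 2.5)),
        ],
    )
    def test_average_ranks(self, values, expected):
        np.testing.assert_allclose(srd.rank_with_ties(values), expected)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            srd.rank_with_ties([1.0])

    @given(st.lists(st.floats(-100, 100), min_size=2, max_size=40))
    @settings(deadline=None, max_examples=50)
    def test_rank_sum_invariant(self, values):
        ranks = srd.rank_with_ties(values)
        n = len(values)
        assert ranks.sum() == pytest.approx(n * (n + 1) / 2)
        assert ranks.min() >= 1 and ranks.max() <= n

    def test_reference_ranking_equals_brute_force(self, rng):
        table = pd.DataFrame(rng.normal(size=(4, 3)))
        expected = srd.rank_with_ties(table.mean(axis=1).to_numpy())
        np.testing.assert_allclose(srd.reference_ranking(table), expected)

    def test_two_identical_columns_share_the_reference(self, rng):
        col = rng.normal(size=8)
        table = pd.DataFrame({"a": col, "b": col})
        np.testing.assert_allclose(srd.reference_ranking(table),
                                   srd.rank_with_ties(col))


class TestSRDValue:
    def test_identical_rankings_give_zero(self):
        assert srd.srd_value([1, 2, 3], [1, 2, 3]) == 0

    def test_reversal_attains_maximum(self):
        assert srd.srd_value([4, 3, 2, 1], [1, 2, 3, 4]) == 8 == srd.srd_max(4)
        assert srd.srd_value([3, 2, 1], [1, 2, 3]) == 4 == srd.srd_max(3)

    def test_srd_max_for_27_objects(self):
        assert srd.srd_max(27) == 364

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            srd.srd_value([1, 2], [1, 2, 3])

    def test_normalization(self):
        assert srd.srd_normalize(0, 10) == 0
        assert srd.srd_normalize(8, 4) == 100.0
        with pytest.raises(ValueError):
            srd.srd_normalize(9, 4)

    @given(st.integers(2, 8), st.integers(0, 10_000))
    @settings(deadline=None, max_examples=60)
    def test_bounds_and_parity_for_permutations(self, n, seed):
        rng = np.random.default_rng(seed)
        perm = rng.permutation(n) + 1
        value = srd.srd_value(perm, np.arange(1, n + 1))
        assert 0 <= value <= srd.srd_max(n)
        assert value % 2 == 0  # tie-free rankings always give even SRD


class TestCRRN:
    def test_exact_n3_distribution(self):
        dist = srd.crrn(3, method="exact")
        np.testing.assert_array_equal(dist.support, [0, 2, 4])
        np.testing.assert_allclose(dist.probabilities, [1 / 6, 2 / 6, 3 / 6])
        assert dist.mean == pytest.approx(8 / 3)

    def test_exact_n2_distribution(self):
        dist = srd.crrn(2, method="exact")
        np.testing.assert_array_equal(dist.support, [0, 2])
        np.testing.assert_allclose(dist.probabilities, [0.5, 0.5])

    @pytest.mark.parametrize("n", [4, 5, 6])
    def test_exact_matches_brute_force_enumeration(self, n):
        dist = srd.crrn(n, method="exact")
        ident = np.arange(n)
        counts = {}
        for perm in itertools.permutations(range(n)):
            v = int(np.abs(np.array(perm) - ident).sum())
            counts[v] = counts.get(v, 0) + 1
        support = sorted(counts)
        np.testing.assert_array_equal(dist.support, support)
        np.testing.assert_allclose(
            dist.probabilities,
            [counts[s] / math.factorial(n) for s in support],
        )

    @pytest.mark.parametrize("n", [3, 5, 8, 10])
    def test_exact_mean_is_analytic(self, n):
        # E[sum |pi(i) - i|] = (n^2 - 1) / 3
        assert srd.crrn(n, method="exact").mean == pytest.approx((n * n - 1) / 3)

    def test_exact_beyond_limit_suggests_monte_carlo(self):
        with pytest.raises(ValueError, match="monte_carlo"):
            srd.crrn(11, method="exact")

    @pytest.mark.parametrize("n", [4, 6, 8])
    def test_monte_carlo_agrees_with_exact(self, n):
        exact = srd.crrn(n, method="exact")
        mc = srd.crrn(n, method="monte_carlo", n_draws=100_000, seed=7)
        # quantiles agree within the discreteness of the even support
        for lv, q in exact.quantiles.items():
            assert abs(mc.quantiles[lv] - q) <= 2
        se = np.std(mc.draws) / np.sqrt(mc.draws.size)
        assert abs(mc.mean - exact.mean) <= 3 * se

    def test_monte_carlo_is_seed_reproducible(self):
        a = srd.crrn(12, method="monte_carlo", n_draws=5_000, seed=3)
        b = srd.crrn(12, method="monte_carlo", n_draws=5_000, seed=3)
        np.testing.assert_array_equal(a.draws, b.draws)


class TestWilcoxon:
    def test_identical_samples_flagged(self):
        res = srd.wilcoxon_matched_pairs([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.all_zero and res.pvalue == 1.0

    def test_six_positive_differences_exact_p(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        res = srd.wilcoxon_matched_pairs(x + np.array([1, 2, 3, 4, 5, 6]) * 0.1, x)
        assert res.pvalue == pytest.approx(2 / 2**6)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_sign_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        d = rng.normal(size=8)
        while np.unique(np.abs(d)).size < d.size or np.any(d == 0):
            d = rng.normal(size=8)
        res = srd.wilcoxon_matched_pairs(d, np.zeros(8))
        ranks = srd.rank_with_ties(np.abs(d))
        w_obs = min(ranks[d > 0].sum(), ranks[d < 0].sum())
        count = 0
        for signs in itertools.product([0, 1], repeat=8):
            w_plus = ranks[np.array(signs, dtype=bool)].sum()
            w = min(w_plus, ranks.sum() - w_plus)
            if w <= w_obs:
                count += 1
        assert res.pvalue == pytest.approx(count / 2**8)


class TestSRDAnalysis:
    def test_measure_equal_to_row_mean_scores_zero(self, rng):
        base = pd.DataFrame(rng.normal(size=(10, 3)), columns=list("abc"))
        from lipochemo.transforms import range_scale_columns
        scaled = range_scale_columns(base)
        base["consensus"] = scaled.mean(axis=1)
        res = srd.srd_analysis(base[["consensus", "a", "b", "c"]],
                               crrn_method=None)
        assert res.srd_raw["consensus"] == 0
        assert res.ordering[0] == "consensus"

    def test_fixture_ranking_matches_reported_ordering(self, panel):
        res = srd.srd_analysis(panel, crrn_method=None)
        assert res.ordering[0] == "Consensus LogP"
        assert set(res.ordering[-3:]) == {"logkw_CN", "CHI_logD", "logkw_Ph"}

    def test_crossvalidation_shape_and_best_median(self, panel):
        res = srd.srd_analysis(panel, crrn_method=None)
        cv = res.crossvalidate(k=7, seed=0)
        assert cv.shape == (7, panel.shape[1])
        assert cv.median().idxmin() == "Consensus LogP"

    def test_fold_computation_equals_direct_subtable_analysis(self, panel):
        cv = srd.srd_crossvalidate(panel, k=7, seed=5)
        rng_folds = np.random.default_rng(5)
        folds = np.array_split(rng_folds.permutation(len(panel)), 7)
        keep = np.setdiff1d(np.arange(len(panel)), folds[0])
        direct = srd.srd_analysis(panel.iloc[keep], crrn_method=None)
        np.testing.assert_allclose(cv.iloc[0].to_numpy(),
                                   direct.srd_pct[cv.columns].to_numpy())

    def test_k_out_of_range_rejected(self, panel):
        with pytest.raises(ValueError):
            srd.srd_crossvalidate(panel, k=1)
        with pytest.raises(ValueError):
            srd.srd_crossvalidate(panel, k=len(panel) + 1)

    def test_wilcoxon_matrix_is_symmetric_probability(self, panel):
        res = srd.srd_analysis(panel, crrn_method=None)
        cv = res.crossvalidate(k=7, seed=0)
        sub = cv[res.ordering[:4]]
        p = res.wilcoxon_matrix(sub)
        np.testing.assert_allclose(p.to_numpy(), p.to_numpy().T)
        assert ((p.to_numpy() >= 0) & (p.to_numpy() <= 1)).all()

    def test_lowest_noise_measure_wins_in_synthetic_tables(self):
        noise = np.array([0.1, 1.0, 1.0, 1.0, 1.0, 1.0])
        wins = 0
        for seed in range(100):
            data = make_lipo_table(n_compounds=27, n_measures=6,
                                   noise_sds=noise, seed=seed)
            res = srd.srd_analysis(data.table, crrn_method=None)
            wins += res.ordering[0] == "M01"
        assert wins >= 95
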