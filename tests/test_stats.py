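"""The statistical layer: summaries, post-hocs, PERMANOVA, LDA, chi-square."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from mousesong.context import PairNightCounts
from mousesong.errors import ValidationError
from mousesong.stats import (
    chisq_type_usage,
    fisher_lda,
    pairwise_wilcoxon,
    permanova_restricted,
    summarize_counts,
    trial_consistency,
)


class TestSummarizeCounts:
    def test_night1_all_regions(self, table1):
        s = summarize_counts(table1, night=1)
        assert s.n == 12
        assert s.mean == pytest.approx(26.67, abs=0.005)
        assert s.sd == pytest.approx(10.94, abs=0.005)

    def test_night3_respects_exclusion(self, table1):
        s = summarize_counts(table1, night=3)
        assert s.n == 11
        assert s.mean == pytest.approx(58.27, abs=0.005)

    def test_night4_includes_male_bedding(self, table1):
        s = summarize_counts(table1, night=4, include_mb=True)
        assert s.n == 6
        assert s.mean == pytest.approx(44.17, abs=0.005)

    def test_contact_corner_drop_zero(self, table1):
        s = summarize_counts(table1, night=1, region="CC",
                             zero_policy="drop_zero")
        assert s.n == 10
        assert s.mean == pytest.approx(17.7, abs=0.005)
        assert s.sd == pytest.approx(9.66, abs=0.005)

    def test_single_pair_has_no_sd(self):
        rows = [PairNightCounts("A", 1, {"FR": 3, "NR": 0, "CC": 0, "CR": 0})]
        s = summarize_counts(rows, night=1)
        assert s.mean == 3.0 and s.sd is None and s.n == 1

    def test_empty_selection_raises(self):
        with pytest.raises(ValidationError):
            summarize_counts([], night=1)


class TestPairwiseWilcoxon:
    def test_bonferroni_thresholds(self):
        groups = {k: np.arange(5) + i for i, k in enumerate("abcd")}
        out = pairwise_wilcoxon(groups, alpha=0.05)
        assert out.attrs["m"] == 6
        assert out.attrs["threshold"] == pytest.approx(0.05 / 6)  # 0.0083
        out3 = pairwise_wilcoxon({k: np.arange(5) + i
                                  for i, k in enumerate("abc")}, alpha=0.05)
        assert out3.attrs["threshold"] == pytest.approx(0.05 / 3)  # 0.016

    def test_identical_paired_samples_not_significant(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        out = pairwise_wilcoxon({"a": x, "b": x.copy()}, paired=True)
        assert out.loc[0, "p"] == 1.0
        assert not out.loc[0, "significant"]

    def test_paired_length_mismatch_raises(self):
        with pytest.raises(ValidationError):
            pairwise_wilcoxon({"a": np.arange(4), "b": np.arange(5)},
                              paired=True)

    def test_matches_scipy_directly(self, rng):
        x, y = rng.normal(0, 1, 20), rng.normal(1, 1, 20)
        out = pairwise_wilcoxon({"a": x, "b": y})
        expected = sps.mannwhitneyu(x, y, alternative="two-sided").pvalue
        assert out.loc[0, "p"] == pytest.approx(expected)


class TestTrialConsistency:
    def test_fixture_reproduces_reported_correlation(self, table1):
        r, p = trial_consistency(table1)
        assert r == pytest.approx(0.97, abs=0.005)
        assert p == pytest.approx(0.006, abs=0.0005)

    def test_perfect_linear_relation(self):
        rows = []
        for i, tot in enumerate((10, 20, 30, 40)):
            rows.append(PairNightCounts(
                f"P{i}", 1, {"FR": tot, "NR": 0, "CC": 0, "CR": 0},
                repetition_total=2 * tot))
        r, _ = trial_consistency(rows)
        assert r == pytest.approx(1.0)

    def test_fewer_than_three_pairs_raises(self):
        rows = [PairNightCounts(f"P{i}", 1, {"FR": 5, "NR": 0, "CC": 0,
                                             "CR": 0}, repetition_total=5)
                for i in range(2)]
        with pytest.raises(ValidationError):
            trial_consistency(rows)


class TestPermanova:
    def test_univariate_equals_classical_anova_f(self, rng):
        x = rng.normal(size=24)
        g = np.repeat([0, 1, 2, 3], 6)
        res = permanova_restricted(x[:, None], g, n_perm=99, seed=7)
        F = sps.f_oneway(*[x[g == k] for k in range(4)]).statistic
        assert res.pseudo_F == pytest.approx(F, abs=1e-10)

    def test_matches_scikit_bio_on_unrestricted_design(self, rng):
        pytest.importorskip("skbio")
        from skbio.stats.distance import DistanceMatrix, permanova as skbio_perm

        X = rng.normal(size=(18, 3))
        g = np.repeat(["a", "b", "c"], 6)
        res = permanova_restricted(X, g, n_perm=99, seed=0,
                                   standardize=False)
        D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2))
        sk = skbio_perm(DistanceMatrix(D), g.tolist(), permutations=99)
        assert res.pseudo_F == pytest.approx(sk["test statistic"], abs=1e-8)

    def test_p_value_bit_reproducible_given_seed(self, rng):
        X = rng.normal(size=(24, 4))
        g = np.repeat([0, 1, 2], 8)
        blocks = np.tile(np.repeat([0, 1, 2, 3], 2), 3)
        r1 = permanova_restricted(X, g, blocks=blocks, n_perm=199, seed=42)
        r2 = permanova_restricted(X, g, blocks=blocks, n_perm=199, seed=42)
        assert r1.p == r2.p and r1.pseudo_F == r2.pseudo_F

    def test_restriction_separates_block_confounding(self, rng):
        # strong block effect, no group effect: unrestricted permutations
        # would see block variance as signal; restricted ones must not
        n_blocks, per_block = 6, 4
        blocks = np.repeat(np.arange(n_blocks), per_block)
        g = np.tile([0, 0, 1, 1], n_blocks)
        X = rng.normal(size=(blocks.size, 2)) + 5.0 * blocks[:, None]
        res = permanova_restricted(X, g, blocks=blocks, n_perm=199, seed=3)
        assert res.p > 0.05

    def test_identical_rows_degenerate(self):
        X = np.ones((10, 2))
        g = np.repeat([0, 1], 5)
        res = permanova_restricted(X, g, n_perm=99, seed=0)
        assert res.degenerate and res.p == 1.0

    def test_all_singleton_blocks_raise(self, rng):
        X = rng.normal(size=(6, 2))
        with pytest.raises(ValidationError):
            permanova_restricted(X, np.repeat([0, 1], 3),
                                 blocks=np.arange(6), n_perm=9, seed=0)

    def test_null_rejection_rate_within_binomial_band(self, rng):
        # 2 groups, 6 blocks of 4, labels exchangeable within blocks
        n_sims, n_perm, alpha = 200, 99, 0.05
        blocks = np.repeat(np.arange(6), 4)
        base = np.tile([0, 0, 1, 1], 6)
        rejections = 0
        for s in range(n_sims):
            x = rng.normal(size=(24, 1))
            g = base.copy()
            for b in range(6):
                idx = np.flatnonzero(blocks == b)
                g[idx] = rng.permutation(g[idx])
            res = permanova_restricted(x, g, blocks=blocks,
                                       n_perm=n_perm, seed=int(s))
            rejections += res.p <= alpha
        lo, hi = sps.binom.interval(0.99, n_sims, alpha)
        assert lo <= rejections <= hi


class TestFisherLda:
    def test_separated_clouds_put_trace_on_ld1(self, rng):
        X = np.vstack([rng.normal([0, 0], 0.5, (50, 2)),
                       rng.normal([6, 0], 0.5, (50, 2)),
                       rng.normal([12, 0], 0.5, (50, 2))])
        g = np.repeat([0, 1, 2], 50)
        res = fisher_lda(X, g)
        assert res.trace_proportions[0] > 0.99

    def test_trace_proportions_sum_to_one(self, rng):
        for _ in range(5):
            X = rng.normal(size=(40, 5))
            g = rng.integers(0, 3, 40)
            if len(np.unique(g)) < 3:
                continue
            res = fisher_lda(X, g)
            assert res.trace_proportions.sum() == pytest.approx(1.0)
            assert (res.trace_proportions >= 0).all()

    def test_matches_sklearn_eigenvalue_shares(self, rng):
        pytest.importorskip("sklearn")
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        X = rng.normal(size=(60, 4)) + np.repeat(
            rng.normal(size=(3, 4)) * 3, 20, axis=0)
        g = np.repeat([0, 1, 2], 20)
        res = fisher_lda(X, g)
        sk = LinearDiscriminantAnalysis(solver="eigen").fit(X, g)
        np.testing.assert_allclose(res.trace_proportions,
                                   sk.explained_variance_ratio_, atol=1e-8)

    def test_duplicated_column_regularized_with_warning(self, rng):
        x = rng.normal(size=(30, 1))
        X = np.hstack([x, x])
        g = np.repeat([0, 1], 15)
        with pytest.warns(RuntimeWarning, match="singular"):
            res = fisher_lda(X, g)
        assert np.isfinite(res.loadings.to_numpy()).all()

    def test_projections_invariant_to_feature_rescaling(self, rng):
        X = rng.normal(size=(45, 3)) + np.repeat(
            rng.normal(size=(3, 3)) * 2, 15, axis=0)
        g = np.repeat([0, 1, 2], 15)
        base = fisher_lda(X, g).projections
        Xs = X * np.array([10.0, 0.1, 3.0]) + np.array([5.0, -2.0, 0.0])
        scaled = fisher_lda(Xs, g).projections
        for k in range(base.shape[1]):
            c = np.corrcoef(base[:, k], scaled[:, k])[0, 1]
            assert abs(c) == pytest.approx(1.0, abs=1e-8)


class TestChisq:
    def test_hand_calculated_2x2(self):
        res = chisq_type_usage(np.array([[10, 0], [0, 10]]))
        assert res.statistic == pytest.approx(20.0)
        assert res.df == 1

    def test_proportional_rows_give_zero(self):
        res = chisq_type_usage(np.array([[10, 20, 30], [1, 2, 3]]))
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_two_regions_thirteen_types_df_12(self, rng):
        table = rng.integers(1, 50, size=(2, 13))
        res = chisq_type_usage(table)
        assert res.df == 12

    def test_zero_column_dropped_with_warning(self):
        table = pd.DataFrame([[5, 0, 3], [2, 0, 9]],
                             columns=["SFL", "TRS", "LFS"])
        with pytest.warns(RuntimeWarning, match="TRS"):
            res = chisq_type_usage(table)
        assert res.df == 1
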