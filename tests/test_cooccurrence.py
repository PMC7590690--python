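from math import comb

import numpy as np
import pandas as pd
import pytest

from immunoscape.cooccurrence import (
    burden_scores,
    category_distribution,
    collapse_category,
    fisher_2x2,
    heterogeneity_distances,
    ks_compare,
    per_sample_pathway_calls,
    score_expression_regression,
)
from immunoscape.mutation import MutationSet
from immunoscape.types import ClinicalTable

from conftest import make_expression


def _mutset(matrix):
    return MutationSet(matrix, matrix.sum(axis=0).astype(int))


class TestBurdenScores:
    def test_counting(self, rng):
        samples = [f"s{i}" for i in range(6)]
        genes = [f"G{i}" for i in range(5)]
        m = pd.DataFrame(rng.integers(0, 2, size=(5, 6)).astype(np.int8),
                         index=genes, columns=samples)
        calls = pd.DataFrame(rng.integers(0, 2, size=(3, 6)).astype(bool),
                             index=["P1", "P2", "P3"], columns=samples)
        flagged = ["G0", "G2", "G3"]
        out = burden_scores(_mutset(m), flagged, calls)
        for s in samples:
            assert out.loc[s, "nssm_score"] == sum(m.loc[g, s] for g in flagged)
            assert out.loc[s, "pathway_score"] == calls[s].sum()

    def test_no_active_pathway_scores_zero(self):
        m = pd.DataFrame([[1, 0]], index=["G"], columns=["a", "b"]).astype(np.int8)
        calls = pd.DataFrame(False, index=["P"], columns=["a", "b"])
        out = burden_scores(_mutset(m), ["G"], calls)
        assert (out["pathway_score"] == 0).all()

    def test_missing_flagged_gene_warns(self):
        m = pd.DataFrame([[1]], index=["G"], columns=["a"]).astype(np.int8)
        calls = pd.DataFrame(columns=["a"])
        with pytest.warns(UserWarning, match="absent"):
            burden_scores(_mutset(m), ["G", "NOPE"], calls)


class TestCollapseCategory:
    @pytest.mark.parametrize("score,cap,expected",
                             [(14, 10, 10), (10, 10, 10), (0, 10, 0),
                              (3, 10, 3)])
    def test_examples(self, score, cap, expected):
        assert collapse_category(score, cap) == expected

    def test_negative_score_is_error(self):
        with pytest.raises(ValueError, match="nonnegative"):
            collapse_category(-1, 10)

    def test_idempotent_and_monotone(self, rng):
        scores = rng.integers(0, 30, size=50)
        once = collapse_category(scores, 10)
        assert (collapse_category(once, 10) == once).all()
        order = np.argsort(scores)
        assert (np.diff(once[order]) >= 0).all()


class TestCategoryDistribution:
    def test_twelve_of_thirteen_structure(self):
        # 13 samples: 12 in category 1, one in category 0
        samples = [f"s{i}" for i in range(13)]
        cats = pd.Series([0] + [1] * 12, index=samples)
        clin = ClinicalTable(pd.DataFrame({"tumor_type": ["CH"] * 13},
                                          index=samples))
        out = category_distribution(cats, clin, cap=10)
        assert out.loc["CH", 0] == pytest.approx(100 / 13)
        assert out.loc["CH", 1] == pytest.approx(1200 / 13)
        assert out.loc["CH", 2:].sum() == 0

    def test_single_sample_one_hot(self):
        clin = ClinicalTable(pd.DataFrame({"tumor_type": ["T"]}, index=["s"]))
        out = category_distribution(pd.Series([4], index=["s"]), clin, cap=10)
        assert out.loc["T", 4] == 100.0
        assert out.loc["T"].sum() == pytest.approx(100.0)

    def test_rows_sum_to_100(self, rng):
        samples = [f"s{i}" for i in range(60)]
        cats = pd.Series(rng.integers(0, 11, size=60), index=samples)
        clin = ClinicalTable(pd.DataFrame(
            {"tumor_type": rng.choice(["A", "B", "C"], 60)}, index=samples))
        out = category_distribution(cats, clin, cap=10)
        np.testing.assert_allclose(out.sum(axis=1), 100.0, atol=1e-9)


class TestHeterogeneityDistances:
    def test_identical_types_all_zero(self):
        dist = pd.DataFrame([[50.0, 50.0]] * 3, index=list("abc"))
        np.testing.assert_allclose(heterogeneity_distances(dist), 0.0)

    def test_two_opposite_types(self):
        dist = pd.DataFrame([[100.0, 0.0], [0.0, 100.0]], index=["a", "b"])
        out = heterogeneity_distances(dist)
        np.testing.assert_allclose(out, np.sqrt(50 ** 2 + 50 ** 2))

    def test_matches_explicit_sum_of_squares(self, rng):
        x = rng.uniform(size=(5, 11))
        x = x / x.sum(axis=1, keepdims=True) * 100
        dist = pd.DataFrame(x, index=[f"t{i}" for i in range(5)])
        out = heterogeneity_distances(dist)
        mean = x.mean(axis=0)
        for i in range(5):
            expected = np.sqrt(((x[i] - mean) ** 2).sum())
            assert out.iloc[i] == pytest.approx(expected, abs=1e-12)

    def test_invariant_to_category_permutation(self, rng):
        x = rng.uniform(size=(4, 6)) * 100
        dist = pd.DataFrame(x, index=list("abcd"))
        perm = rng.permutation(6)
        permuted = pd.DataFrame(x[:, perm], index=list("abcd"))
        np.testing.assert_allclose(heterogeneity_distances(dist),
                                   heterogeneity_distances(permuted))


class TestKsCompare:
    def test_identical_samples(self):
        d, p = ks_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert d == 0.0
        assert p == pytest.approx(1.0)

    def test_disjoint_small_samples_exact_p(self):
        # D = 1; exact two-sided p = 2/C(6,3) = 0.1
        d, p = ks_compare([1.0, 2.0, 3.0], [10.0, 11.0, 12.0])
        assert d == 1.0
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_null_rejection_rates_calibrated(self):
        """Exact KS p-values are discrete for n=30 (sub-uniform by
        construction); the tail rejection rates must be valid and not
        grossly conservative."""
        rng = np.random.default_rng(7)
        ps = []
        for _ in range(1000):
            a, b = rng.normal(size=30), rng.normal(size=30)
            ps.append(ks_compare(a, b)[1])
        ps = np.asarray(ps)
        for alpha in (0.01, 0.05, 0.10):
            rate = (ps < alpha).mean()
            assert rate <= alpha + 0.02        # validity (+ MC margin)
            assert rate >= alpha / 4           # not absurdly conservative


class TestScoreExpressionRegression:
    def _cohort(self, slope, noise, rng, n_per_cat=20, cats=8):
        scores, expr = [], []
        for c in range(cats):
            scores += [c] * n_per_cat
            expr += list(5.0 + slope * c + rng.normal(0, noise, n_per_cat))
        idx = [f"s{i}" for i in range(len(scores))]
        return pd.Series(scores, index=idx), pd.Series(expr, index=idx)

    def test_exact_line_recovered(self, rng):
        scores, expr = self._cohort(slope=-0.5, noise=0.0, rng=rng)
        fit = score_expression_regression(scores, expr)
        assert fit.chosen_degree == 1
        assert fit.betas[1] == pytest.approx(-0.5, abs=1e-10)
        assert fit.adjusted_r2 == pytest.approx(1.0, abs=1e-9)

    def test_sparse_categories_dropped(self, rng):
        scores, expr = self._cohort(slope=-0.3, noise=0.1, rng=rng)
        # add a category with too few samples; it must not affect the fit
        scores2 = pd.concat([scores, pd.Series([40], index=["extra"])])
        expr2 = pd.concat([expr, pd.Series([99.0], index=["extra"])])
        a = score_expression_regression(scores, expr)
        b = score_expression_regression(scores2, expr2,
                                        min_samples_per_category=10)
        assert list(a.points["score"]) == list(b.points["score"])

    def test_too_few_categories_is_error(self, rng):
        scores = pd.Series([0] * 15 + [1] * 15, index=[f"s{i}" for i in range(30)])
        expr = pd.Series(rng.normal(size=30), index=scores.index)
        with pytest.raises(ValueError, match="categories"):
            score_expression_regression(scores, expr)

    def test_cubic_signal_beats_linear(self, rng):
        scores, expr = self._cohort(slope=0.0, noise=0.0, rng=rng)
        expr = expr + 0.05 * scores ** 3
        fit = score_expression_regression(scores, expr)
        assert fit.chosen_degree > 1

    def test_null_slope_p_roughly_uniform(self):
        rng = np.random.default_rng(11)
        ps = []
        for _ in range(300):
            scores, expr = self._cohort(slope=0.0, noise=1.0, rng=rng)
            ps.append(score_expression_regression(scores, expr).slope_p)
        ps = np.asarray(ps)
        assert abs((ps < 0.05).mean() - 0.05) < 0.04
        from scipy import stats as sps
        assert sps.kstest(ps, "uniform").statistic < 0.10


class TestPerSamplePathwayCalls:
    def test_median_split_rule(self, rng):
        x = rng.normal(size=(4, 10))
        m = make_expression(x)
        calls = per_sample_pathway_calls(m, {"P": ["g0", "g1", "g2", "g3"]})
        vals = np.median(x, axis=0)
        expected = vals > np.median(vals)
        np.testing.assert_array_equal(calls.loc["P"].to_numpy(), expected)

    def test_stratified_threshold_is_within_stratum(self, rng):
        x = rng.normal(size=(2, 8))
        x[:, 4:] += 100.0  # second stratum much higher overall
        m = make_expression(x)
        strata = pd.Series(["A"] * 4 + ["B"] * 4,
                           index=[f"s{j}" for j in range(8)])
        calls = per_sample_pathway_calls(m, {"P": ["g0", "g1"]}, strata)
        # each stratum is split around its own median: 2 active out of 4
        assert calls.loc["P", [f"s{j}" for j in range(4)]].sum() == 2
        assert calls.loc["P", [f"s{j}" for j in range(4, 8)]].sum() == 2


class TestFisher:
    def test_matches_hypergeometric_enumeration(self):
        table = np.array([[8, 2], [1, 5]])
        _, p = fisher_2x2(table)
        # enumerate all tables with the same margins
        r1, r2 = table.sum(axis=1)
        c1 = table[:, 0].sum()
        n = table.sum()
        def prob(a):
            return comb(r1, a) * comb(r2, c1 - a) / comb(n, c1)
        p_obs = prob(table[0, 0])
        expected = sum(prob(a) for a in range(max(0, c1 - r2), min(r1, c1) + 1)
                       if prob(a) <= p_obs + 1e-12)
        assert p == pytest.approx(expected, abs=1e-10)

    def test_bad_shape_is_error(self):
        with pytest.raises(ValueError):
            fisher_2x2([[1, 2, 3], [4, 5, 6]])
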