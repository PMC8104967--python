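"""Pair correlations, rank percentile, clustering, trend test, ratios."""

import numpy as np
import pandas as pd
import pytest
import scipy.cluster.hierarchy as sch
import scipy.stats

from bdgcoex import (
    ExpressionMatrix,
    coexpression_dendrogram,
    correlation_distribution,
    expression_ratio,
    linear_trend_test,
    pair_correlations,
    rank_percentile,
    spearman_correlation,
)


def _matrix(values, gene_ids=None, cell_ids=None):
    g, c = values.shape
    return ExpressionMatrix(
        values,
        gene_ids or [f"g{i}" for i in range(g)],
        cell_ids or [f"s{j}" for j in range(c)],
    )


def _pairs(*tuples):
    return pd.DataFrame({"minus_gene": [a for a, _ in tuples],
                         "plus_gene": [b for _, b in tuples]})


class TestPairCorrelations:
    def test_identical_vectors_give_r_one(self, rng):
        v = rng.gamma(2, 1, 30)
        m = _matrix(np.vstack([v, v]))
        (pc,) = pair_correlations(m, _pairs(("g0", "g1")))
        assert pc.status == "ok" and pc.r == pytest.approx(1.0)

    def test_constant_gene_flagged_zero_variance(self, rng):
        m = _matrix(np.vstack([np.full(20, 3.0), rng.gamma(2, 1, 20)]))
        (pc,) = pair_correlations(m, _pairs(("g0", "g1")))
        assert pc.status == "zero_variance" and pc.r is None

    def test_missing_gene_flagged(self, rng):
        m = _matrix(rng.gamma(2, 1, (2, 20)))
        (pc,) = pair_correlations(m, _pairs(("g0", "absent")))
        assert pc.status == "missing_gene"

    def test_matches_covariance_formula_oracle(self, rng):
        values = rng.gamma(2.0, 1.0, size=(200, 100))
        m = _matrix(values)
        idx = rng.choice(200, size=(50, 2), replace=False)
        pairs = _pairs(*[(f"g{a}", f"g{b}") for a, b in idx])
        for pc, (a, b) in zip(pair_correlations(m, pairs), idx):
            x, y = values[a], values[b]
            r_oracle = ((x - x.mean()) * (y - y.mean())).mean() / (x.std() * y.std())
            assert pc.r == pytest.approx(r_oracle, abs=1e-12)

    def test_invariant_under_positive_affine_transform(self, rng):
        values = rng.gamma(2.0, 1.0, size=(2, 50))
        r0 = pair_correlations(_matrix(values), _pairs(("g0", "g1")))[0].r
        scaled = np.vstack([3.5 * values[0] + 2.0, 0.25 * values[1] + 7.0])
        r1 = pair_correlations(_matrix(scaled), _pairs(("g0", "g1")))[0].r
        assert r1 == pytest.approx(r0, abs=1e-12)

    def test_empty_pair_list_errors(self, rng):
        with pytest.raises(ValueError, match="empty"):
            pair_correlations(_matrix(rng.gamma(2, 1, (2, 20))), _pairs())


class TestRankPercentile:
    def test_examples(self):
        values = [0.9, 0.5, 0.1, -0.2]
        assert rank_percentile(values, 0.9) == 25.0
        assert rank_percentile(values, -0.2) == 100.0

    def test_matches_sort_and_count_bruteforce(self, rng):
        values = rng.uniform(-1, 1, 1000)
        queries = rng.choice(values, 100)
        for q in queries:
            brute = 100.0 * sum(1 for v in sorted(values) if v >= q) / len(values)
            assert rank_percentile(values, q) == pytest.approx(brute)

    def test_monotone_non_increasing_and_bounded(self, rng):
        values = rng.uniform(-1, 1, 500)
        qs = np.sort(rng.choice(values, 50))
        pcts = [rank_percentile(values, q) for q in qs]
        assert all(a >= b for a, b in zip(pcts, pcts[1:]))
        assert all(0 < p <= 100 for p in pcts)

    def test_distribution_query_reporting(self, rng):
        values = rng.gamma(2.0, 1.0, size=(4, 30))
        values[1] = values[0] * 2 + rng.normal(0, 0.01, 30)  # near-perfect pair
        m = _matrix(values)
        pcs = pair_correlations(m, _pairs(("g0", "g1"), ("g2", "g3")))
        dist = correlation_distribution(pcs, query=("g0", "g1"))
        assert dist.n_pairs == 2
        assert dist.query_percentile == 50.0  # top pair of two

    def test_unscored_query_errors_with_status(self, rng):
        values = rng.gamma(2.0, 1.0, size=(2, 30))
        values[0] = 1.0
        pcs = pair_correlations(_matrix(values), _pairs(("g0", "g1")))
        with pytest.raises(ValueError, match="zero_variance"):
            correlation_distribution(pcs, query=("g0", "g1"))


class TestSpearman:
    def test_monotone_map_gives_rho_one(self):
        x = np.array([3.0, 1.0, 4.0, 1.5, 9.0, 2.6])
        rho, _ = spearman_correlation(x, np.exp(x))
        assert rho == pytest.approx(1.0)
        rho, _ = spearman_correlation(x, -x**3)
        assert rho == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle(self, rng):
        x, y = rng.normal(size=20), rng.normal(size=20)
        rho, p = spearman_correlation(x, y)
        rx, ry = scipy.stats.rankdata(x), scipy.stats.rankdata(y)
        r_oracle = np.corrcoef(rx, ry)[0, 1]
        assert rho == pytest.approx(r_oracle, abs=1e-12)

    def test_constant_vector_errors(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_correlation(np.ones(10), np.arange(10.0))


class TestDendrogram:
    def test_identical_genes_merge_first(self, rng):
        a = rng.normal(size=40)
        values = np.vstack([a, a, rng.normal(size=40)]) + 10.0
        m = _matrix(values, gene_ids=["A", "B", "C"])
        corr, Z, leaves, top = coexpression_dendrogram(m, ["A", "B", "C"])
        assert Z[0, 2] == pytest.approx(0.0, abs=1e-12)  # first merge at distance 0
        assert set(leaves[:2]) == {"A", "B"} or set(leaves[-2:]) == {"A", "B"}
        assert top.set_index("gene").loc["A", "top_partner"] == "B"

    def test_linkage_matches_bruteforce_average_linkage(self, rng):
        values = rng.normal(size=(10, 60)) + 10.0
        m = _matrix(values)
        genes = sorted(m.gene_ids)
        corr, Z, _, _ = coexpression_dendrogram(m, m.gene_ids)
        # oracle: naive O(n^3) average linkage over 1 - r, cophenetic check
        D = 1.0 - np.corrcoef(np.vstack([m.gene_vector(g) for g in genes]))
        clusters = {i: [i] for i in range(10)}
        coph = np.zeros((10, 10))
        while len(clusters) > 1:
            keys = sorted(clusters)
            best = None
            for i in keys:
                for j in keys:
                    if i >= j:
                        continue
                    d = np.mean([D[a, b] for a in clusters[i] for b in clusters[j]])
                    if best is None or d < best[0]:
                        best = (d, i, j)
            d, i, j = best
            for a in clusters[i]:
                for b in clusters[j]:
                    coph[a, b] = coph[b, a] = d
            clusters[min(i, j)] = clusters.pop(i) + clusters.pop(j)
        got = sch.cophenet(Z)
        expected = coph[np.triu_indices(10, k=1)]
        np.testing.assert_allclose(got, expected, atol=1e-10)

    def test_result_independent_of_gene_order(self, rng):
        values = rng.normal(size=(6, 50)) + 10.0
        m = _matrix(values)
        ref = coexpression_dendrogram(m, m.gene_ids)
        shuffled = list(rng.permutation(m.gene_ids))
        out = coexpression_dendrogram(m, shuffled)
        assert out[2] == ref[2]                      # same leaf order
        pd.testing.assert_frame_equal(out[0], ref[0])

    def test_missing_gene_errors_with_ids(self, rng):
        m = _matrix(rng.normal(size=(3, 30)) + 10.0)
        with pytest.raises(KeyError, match="nope"):
            coexpression_dendrogram(m, ["g0", "g1", "nope"])


class TestLinearTrend:
    def test_two_groups_equal_pooled_t(self, rng):
        x = rng.normal(0, 1, 12)
        y = rng.normal(0.8, 1, 17)
        res = linear_trend_test(
            np.concatenate([x, y]), np.array([0] * 12 + [1] * 17)
        )
        t_ref, p_ref = scipy.stats.ttest_ind(y, x, equal_var=True)
        assert res.t == pytest.approx(t_ref, abs=1e-10)
        assert res.p == pytest.approx(p_ref, abs=1e-10)
        assert res.df == 27

    def test_symmetric_means_give_zero_slope(self):
        values = np.array([3.0, 3.0, 5.0, 5.0, 3.0, 3.0]) + np.tile([-0.1, 0.1], 3)
        group = np.array([1, 1, 2, 2, 3, 3])
        res = linear_trend_test(values, group)
        assert res.slope == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0, abs=1e-12)

    def test_contrast_coefficients_sum_to_zero(self, rng):
        values = rng.normal(size=30)
        group = rng.integers(0, 5, 30)
        group[:5] = np.arange(5)  # every group populated
        res = linear_trend_test(values, group)
        assert res.coefficients.sum() == pytest.approx(0.0)

    def test_matches_anova_contrast_regression_oracle(self, rng):
        # unequal group sizes, k = 4, vs statsmodels OLS contrast t-test
        import statsmodels.api as sm

        sizes = [5, 9, 7, 12]
        values = np.concatenate([rng.normal(m, 1.3, n) for m, n in zip([0, 1, 1.5, 3], sizes)])
        group = np.concatenate([[i] * n for i, n in enumerate(sizes)])
        res = linear_trend_test(values, group)
        dummies = pd.get_dummies(pd.Series(group)).to_numpy(dtype=float)
        fit = sm.OLS(values, dummies).fit()
        contrast = fit.t_test(res.coefficients)
        assert res.t == pytest.approx(float(np.squeeze(contrast.tvalue)), abs=1e-10)
        assert res.p == pytest.approx(float(np.squeeze(contrast.pvalue)), abs=1e-10)
        assert res.df == len(values) - 4

    def test_all_constant_zero_trend_gives_p_one(self):
        res = linear_trend_test(np.array([2.0, 2.0, 2.0, 2.0]), np.array([1, 1, 2, 2]))
        assert res.p == 1.0

    def test_single_group_errors(self):
        with pytest.raises(ValueError, match="2 groups"):
            linear_trend_test(np.arange(4.0), np.zeros(4))


class TestExpressionRatio:
    def test_equal_genes_give_unit_ratio(self):
        values = np.vstack([np.arange(1.0, 6.0)] * 2)
        m = _matrix(values)
        res = expression_ratio(m, "g0", "g1")
        assert np.allclose(res.ratios, 1.0)
        assert res.n_excluded == 0

    def test_constant_unit_normalizer_is_identity(self, rng):
        values = np.vstack([rng.gamma(2, 1, 8) + 0.1, rng.gamma(2, 1, 8) + 0.1, np.ones(8)])
        m = _matrix(values)
        plain = expression_ratio(m, "g0", "g1")
        normed = expression_ratio(m, "g0", "g1", normalizer="g2")
        np.testing.assert_allclose(normed.ratios, plain.ratios)
        assert normed.normalized and normed.normalizer == "g2"

    def test_matches_elementwise_division_oracle(self, rng):
        values = rng.gamma(2, 1, (3, 25)) + 0.05
        m = _matrix(values)
        res = expression_ratio(m, "g0", "g1", normalizer="g2")
        np.testing.assert_allclose(
            res.ratios.to_numpy(), (values[0] / values[1]) / values[2], rtol=1e-12
        )

    def test_zero_denominator_samples_excluded_and_counted(self):
        values = np.array([[1.0, 2.0, 3.0], [1.0, 0.0, 2.0]])
        m = _matrix(values)
        res = expression_ratio(m, "g0", "g1", group=["a", "a", "b"])
        assert res.n_excluded == 1
        assert list(res.ratios.index) == ["s0", "s2"]
        assert set(res.summary.index) == {"a", "b"}
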