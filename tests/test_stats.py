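from itertools import combinations, permutations

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb
from scipy.stats import rankdata

from pbmscore.io import ExpressionMatrix
from pbmscore.stats import (
    bh_adjust,
    correlate_genes_with_score,
    fisher_exact,
    geneset_enrichment,
    trend_test,
    wilcoxon_rank_sum,
)


def exact_wilcoxon_oracle(x, y):
    """Two-sided exact rank-sum p by enumerating every group assignment."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = rankdata(pooled)
    u_obs = np.sum(rankdata(pooled)[:n1]) - n1 * (n1 + 1) / 2
    center = n1 * len(y) / 2
    count = total = 0
    for idx in combinations(range(len(pooled)), n1):
        u = np.sum(ranks[list(idx)]) - n1 * (n1 + 1) / 2
        total += 1
        if abs(u - center) >= abs(u_obs - center) - 1e-12:
            count += 1
    return count / total


class TestWilcoxon:
    def test_exact_small_example(self):
        res = wilcoxon_rank_sum([3, 4], [1, 2], mode="exact")
        assert res.p_value == pytest.approx(1 / 3)
        assert res.direction == 1

    def test_identical_groups_p_one(self):
        res = wilcoxon_rank_sum([1, 2, 3], [1, 2, 3], mode="approx")
        assert res.p_value == pytest.approx(1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1])

    def test_exact_matches_enumeration_oracle(self, rng):
        """Exact-mode p equals brute-force assignment enumeration for all
        tie-free inputs up to n = 8."""
        for n1 in range(1, 5):
            for n2 in range(1, 9 - n1):
                vals = rng.permutation(np.arange(1.0, n1 + n2 + 1))
                x, y = vals[:n1], vals[n1:]
                res = wilcoxon_rank_sum(x, y, mode="exact")
                assert res.p_value == pytest.approx(exact_wilcoxon_oracle(x, y))

    def test_permutation_invariant_to_input_order(self, rng):
        x = rng.normal(size=9)
        y = rng.normal(size=7)
        a = wilcoxon_rank_sum(x, y, mode="approx")
        b = wilcoxon_rank_sum(rng.permutation(x), rng.permutation(y), mode="approx")
        assert a.p_value == pytest.approx(b.p_value)


def exact_trend_oracle(values, labels, alternative):
    """Enumerate all value permutations and recompute the statistic from
    scratch each time."""
    groups = list(pd.unique(np.asarray(labels)))
    w = np.array([groups.index(g) + 1 for g in labels], dtype=float)
    t_obs = float(np.sum(w * rankdata(values)))
    n = len(values)
    e_t = (n + 1) / 2 * w.sum()
    count = total = 0
    for perm in permutations(values):
        t = float(np.sum(w * rankdata(perm)))
        total += 1
        if alternative == "two-sided":
            hit = abs(t - e_t) >= abs(t_obs - e_t) - 1e-9
        elif alternative == "increasing":
            hit = t >= t_obs - 1e-9
        else:
            hit = t <= t_obs + 1e-9
        count += hit
    return count / total


class TestTrend:
    def test_perfectly_ordered_singletons(self):
        res = trend_test([1, 2, 3], ["a", "b", "c"], mode="exact", alternative="increasing")
        assert res.p_value == pytest.approx(1 / 6)

    def test_identical_values_give_p_one(self):
        res = trend_test([5, 5, 5, 5, 5, 5], ["a", "a", "b", "b", "c", "c"], mode="approx")
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_two_groups_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            trend_test([1, 2], ["a", "b"])

    @pytest.mark.parametrize("alternative", ["two-sided", "increasing"])
    def test_exact_matches_permutation_oracle(self, rng, alternative):
        labels = ["a", "a", "b", "b", "c", "c", "c"]
        values = rng.permutation(np.arange(1.0, 8.0))
        res = trend_test(values, labels, mode="exact", alternative=alternative)
        assert res.p_value == pytest.approx(
            exact_trend_oracle(values, labels, alternative)
        )

    def test_respects_categorical_order_not_appearance(self):
        """An ordered categorical defines the trend direction even when
        levels first appear out of order."""
        lab = pd.Categorical(
            ["c", "a", "b", "c", "a", "b", "c", "a", "b"],
            categories=["a", "b", "c"],
            ordered=True,
        )
        vals = [30, 1, 10, 31, 2, 11, 32, 3, 12]  # increasing along a<b<c
        res = trend_test(np.array(vals, float), lab, mode="approx")
        assert res.statistic > 0


def fisher_oracle(a, b, c, d):
    """Sum hypergeometric probabilities of tables no more likely than the
    observed one, margins fixed."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1, exact=True)

    def prob(x):
        return comb(r1, x, exact=True) * comb(r2, c1 - x, exact=True) / denom

    p_obs = prob(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))


class TestFisher:
    def test_diagonal_table(self):
        assert fisher_exact([[3, 0], [0, 3]]).p_value == pytest.approx(0.1)

    def test_balanced_table_p_one(self):
        assert fisher_exact([[1, 1], [1, 1]]).p_value == pytest.approx(1.0)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margins"):
            fisher_exact([[0, 0], [1, 1]])

    def test_matches_enumeration_for_small_margins(self):
        for a in range(5):
            for b in range(5):
                for c in range(5):
                    for d in range(5):
                        if min(a + b, c + d, a + c, b + d) == 0:
                            continue
                        p = fisher_exact([[a, b], [c, d]]).p_value
                        assert p == pytest.approx(
                            fisher_oracle(a, b, c, d), abs=1e-10
                        )


def bh_oracle(p):
    """Textbook step-up: adj_(i) = min_{j>=i} p_(j) * m / j, clipped at 1."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj_sorted = np.minimum.accumulate(
        (p[order] * m / np.arange(1, m + 1))[::-1]
    )[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj_sorted, 1.0)
    return out


class TestBH:
    def test_equal_spacing_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_p_identity(self):
        assert bh_adjust([0.05])[0] == pytest.approx(0.05)

    def test_clipping(self):
        assert np.allclose(bh_adjust([0.5, 1.0]), [1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_matches_step_up_oracle_on_random_vectors(self, rng):
        for _ in range(1000):
            p = rng.uniform(size=int(rng.integers(1, 25)))
            assert np.allclose(bh_adjust(p), bh_oracle(p), atol=1e-12)


class TestCorrelation:
    def _matrix(self, rows, samples):
        return ExpressionMatrix(
            pd.DataFrame(rows, index=[f"g{i}" for i in range(len(rows))], columns=samples)
        )

    def test_gene_equal_to_score(self):
        m = self._matrix([[1, 2, 3, 4], [4, 3, 2, 1]], list("abcd"))
        score = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        out = correlate_genes_with_score(m, score)
        assert out.loc["g0", "r"] == pytest.approx(1.0)
        assert out.loc["g1", "r"] == pytest.approx(-1.0)

    def test_constant_gene_convention(self):
        m = self._matrix([[5, 5, 5], [1, 2, 3]], list("abc"))
        score = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        out = correlate_genes_with_score(m, score)
        assert out.loc["g0", "r"] == 0.0 and out.loc["g0", "p"] == 1.0

    def test_misaligned_ids_rejected(self):
        m = self._matrix([[1, 2, 3], [3, 2, 1]], list("abc"))
        with pytest.raises(ValueError, match="sample ids"):
            correlate_genes_with_score(m, pd.Series([1.0, 2.0, 3.0], index=list("abd")))

    def test_agrees_with_scipy_per_gene(self, rng):
        from scipy.stats import spearmanr

        vals = rng.normal(size=(10, 30))
        m = self._matrix(list(vals), [f"s{i}" for i in range(30)])
        score = pd.Series(rng.normal(size=30), index=[f"s{i}" for i in range(30)])
        out = correlate_genes_with_score(m, score, method="spearman")
        for i in range(10):
            ref = spearmanr(vals[i], score.to_numpy())
            assert out.iloc[i]["r"] == pytest.approx(ref.statistic, abs=1e-10)
            assert out.iloc[i]["p"] == pytest.approx(ref.pvalue, rel=1e-6)


class TestGenesetEnrichment:
    def test_complete_overlap(self):
        u = [f"g{i}" for i in range(10)]
        res = geneset_enrichment(u[:5], u, u[:5])
        assert res.p_value == pytest.approx(1 / 252)

    def test_minimum_overlap_p_one(self):
        u = [f"g{i}" for i in range(6)]
        res = geneset_enrichment(u[:2], u, u[4:])  # overlap 0 is the minimum
        assert res.p_value == pytest.approx(1.0)

    def test_selected_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            geneset_enrichment(["x"], ["a", "b"], ["a"])
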