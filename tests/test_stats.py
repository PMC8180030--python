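"""Statistical engine: exact tests against enumeration oracles, the
moderated linear model against its least-squares limit, rank products
against exhaustive permutation, clustering recovery."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from ptcore.stats import (
    bh_fdr,
    correlation_cluster,
    cut_two_groups,
    estimate_prior_variance,
    fisher_exact,
    make_design,
    moderated_fit,
    moderated_two_group,
    rank_product,
    rank_product_exhaustive,
    trigamma_inverse,
    wilcoxon_rank_sum,
    zscale_rows,
)


def fisher_oracle(a, b, c, d):
    """Exact two-sided p by integer-arithmetic hypergeometric enumeration."""
    n, r1, c1 = a + b + c + d, a + b, a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    obs = math.comb(r1, a) * math.comb(n - r1, c1 - a)
    num = sum(
        w for x in range(lo, hi + 1)
        if (w := math.comb(r1, x) * math.comb(n - r1, c1 - x)) <= obs
    )
    return num / math.comb(n, c1)


class TestFisher:
    def test_known_table(self):
        res = fisher_exact((1, 9, 11, 3))
        assert res.oddsratio == pytest.approx((1 * 3) / (9 * 11))
        assert res.p == pytest.approx(fisher_oracle(1, 9, 11, 3), abs=1e-12)
        assert res.p == pytest.approx(0.0028, abs=2e-4)

    def test_balanced_table_is_null(self):
        res = fisher_exact((5, 5, 5, 5))
        assert res.oddsratio == 1.0
        assert res.p == pytest.approx(1.0, abs=1e-12)

    def test_zero_cell_uses_haldane_correction(self):
        res = fisher_exact((0, 10, 10, 10))
        assert res.oddsratio == pytest.approx(0.5 * 10.5 / (10.5 * 10.5))
        assert res.ci_low < res.oddsratio < res.ci_high

    def test_degenerate_margin_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact((0, 0, 3, 4))

    def test_agrees_with_scipy_two_sided(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            t = rng.integers(0, 12, 4)
            if min(t[0] + t[1], t[2] + t[3], t[0] + t[2], t[1] + t[3]) == 0:
                continue
            res = fisher_exact(t)
            assert res.p == pytest.approx(
                sps.fisher_exact(t.reshape(2, 2)).pvalue, abs=1e-9)

    @given(st.tuples(*[st.integers(0, 10)] * 4))
    @settings(max_examples=200, deadline=None)
    def test_transposition_and_column_swap(self, table):
        a, b, c, d = table
        if (a + b) * (c + d) * (a + c) * (b + d) == 0:
            return
        res = fisher_exact((a, b, c, d))
        assert res.p == pytest.approx(fisher_exact((a, c, b, d)).p, abs=1e-12)
        swapped = fisher_exact((b, a, d, c))
        assert swapped.oddsratio == pytest.approx(1.0 / res.oddsratio)


class TestWilcoxon:
    def test_fully_separated_small_groups(self):
        u, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert u == 0.0 and p == pytest.approx(0.1)

    def test_identical_multisets(self):
        _, p = wilcoxon_rank_sum([1, 2, 2, 5], [1, 2, 2, 5])
        assert p == 1.0

    def test_shifted_normals_detected(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 200)
        y = rng.normal(1, 1, 200)
        _, p = wilcoxon_rank_sum(x, y)
        assert p < 0.001

    def test_exact_path_matches_scipy(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            x = rng.normal(size=4)
            y = rng.normal(size=5)
            _, p = wilcoxon_rank_sum(x, y)
            ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestModeratedFit:
    def _design(self):
        return make_design(["s"] * 3 + ["r"] * 3, baseline="s")

    def test_d0_zero_reproduces_ols_t_exactly(self):
        rng = np.random.default_rng(5)
        counts = rng.poisson(300, (400, 6))
        libs = np.full(6, 1e6)
        X, c, _ = self._design()
        res = moderated_fit(counts, X, c, weights=False, d0_override=0,
                            lib_sizes=libs)
        y = np.log2((counts + 0.5) / (libs + 1) * 1e6)
        for g in rng.choice(400, 25, replace=False):
            est = y[g, 3:].mean() - y[g, :3].mean()
            ss = ((y[g, :3] - y[g, :3].mean()) ** 2).sum() + (
                (y[g, 3:] - y[g, 3:].mean()) ** 2).sum()
            t_ref = est / math.sqrt(ss / 4 * (2 / 3))
            assert res["t"].iloc[g] == pytest.approx(t_ref, abs=1e-10)
            assert res["log2FC"].iloc[g] == pytest.approx(est, abs=1e-12)

    def test_rank_deficient_design_rejected(self):
        X = np.ones((6, 2))
        with pytest.raises(ValueError):
            moderated_fit(np.ones((10, 6)), X, [0, 1])

    def test_single_replicate_group_rejected(self):
        X = np.column_stack([np.ones(3), [0, 0, 1]])
        with pytest.raises(ValueError):
            moderated_fit(np.ones((10, 3)), X, [0, 1])

    def test_shrinkage_moves_variances_toward_prior(self):
        rng = np.random.default_rng(6)
        counts = rng.poisson(100, (800, 6))
        X, c, _ = self._design()
        res = moderated_fit(counts, X, c)
        assert res.attrs["d0"] > 0
        raw_spread = np.var(np.log(res["s2"][res["s2"] > 0]))
        post_spread = np.var(np.log(res["s2_post"]))
        assert post_spread < raw_spread

    def test_blocked_design_removes_pair_effect(self):
        rng = np.random.default_rng(7)
        G = 300
        base = rng.lognormal(5, 0.5, G)
        pair_fx = {"p1": 1.0, "p2": 2.0, "p3": 0.5}
        counts, conds, blocks = [], [], []
        for pair, fx in pair_fx.items():
            for cond, shift in (("s", 1.0), ("r", 1.0)):
                for _ in range(2):
                    counts.append(rng.poisson(base * fx * shift))
                    conds.append(cond)
                    blocks.append(pair)
        counts = np.column_stack(counts)
        X, c, _ = make_design(conds, blocks=blocks, baseline="s")
        res = moderated_fit(counts, X, c, lfc_cut=1, fdr_cut=0.05)
        assert (res["call"] == "ns").all()


class TestPriorEstimation:
    def test_trigamma_inverse_roundtrip(self):
        from scipy.special import polygamma

        for y in (0.1, 0.5, 2.0, 10.0, 200.0):
            x = float(polygamma(1, y))
            assert trigamma_inverse(x) == pytest.approx(y, rel=1e-6)

    def test_recovers_planted_prior(self):
        rng = np.random.default_rng(8)
        d0, s0_2, df = 8.0, 2.0, 4
        G = 5000
        true_var = s0_2 * d0 / rng.chisquare(d0, G)
        s2 = true_var * rng.chisquare(df, G) / df
        d0_hat, s0_2_hat = estimate_prior_variance(s2, df)
        assert abs(d0_hat - d0) / d0 < 0.3
        assert abs(s0_2_hat - s0_2) / s0_2 < 0.15


class TestModeratedTwoGroup:
    def test_antisymmetric_and_null_centered(self):
        rng = np.random.default_rng(9)
        a = rng.normal(0, 1, (500, 3))
        b = rng.normal(0, 1, (500, 3))
        r1 = moderated_two_group(a, b)
        r2 = moderated_two_group(b, a)
        assert np.allclose(r1["t"], -r2["t"])
        assert abs(np.mean(r1["t"])) < 0.1


class TestRankProduct:
    def _table(self, vals):
        return pd.DataFrame(vals, columns=["p1", "p2"])

    def test_top_gene_has_minimal_rp(self):
        tab = self._table([[5.0, 6.0], [1.0, 2.0], [0.5, 0.1], [-1.0, -2.0]])
        res = rank_product(tab, "up", n_permutations=100, seed=0)
        assert res["RP"].iloc[0] == 1.0
        assert res["RP"].iloc[0] == res["RP"].min()

    def test_geometric_mean_of_ranks(self):
        vals = np.zeros((8, 2))
        vals[:, 0] = -np.arange(8)      # gene 1 ranked 2 in pair 1
        vals[:, 1] = np.arange(8)[::-1]
        vals[1, 0] = -0.5
        tab = self._table(vals)
        res = rank_product(tab, "up", n_permutations=10, seed=0)
        ranks_p1 = sps.rankdata(-vals[:, 0])
        ranks_p2 = sps.rankdata(-vals[:, 1])
        g = 3
        assert res["RP"].iloc[g] == pytest.approx(
            math.sqrt(ranks_p1[g] * ranks_p2[g]))

    def test_permutation_p_matches_exhaustive_small(self):
        tab = self._table([[3.0, 2.5], [1.0, 1.5], [-1.0, 0.5], [-3.0, -2.0]])
        approx = rank_product(tab, "up", n_permutations=4000, seed=1)
        exact = rank_product_exhaustive(tab, "up")
        assert np.allclose(approx["p"], exact["p"], atol=0.05)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(10)
        vals = rng.normal(size=(20, 3))
        tab = pd.DataFrame(vals)
        res1 = rank_product(tab, "down", n_permutations=500, seed=3)
        res2 = rank_product(np.exp(tab) * 7, "down", n_permutations=500, seed=3)
        assert np.array_equal(res1["RP"], res2["RP"])
        assert np.array_equal(res1["p"], res2["p"])

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError):
            rank_product(pd.DataFrame({"p1": [1.0, 2.0]}), "up")


class TestBH:
    @given(st.lists(st.floats(1e-9, 1.0), min_size=2, max_size=40))
    @settings(max_examples=100, deadline=None)
    def test_qvalues_monotone_in_p(self, pvals):
        p = np.array(pvals)
        q = bh_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)
        assert np.all(q >= p - 1e-12)


class TestClustering:
    def test_identical_samples_merge_first(self):
        rng = np.random.default_rng(11)
        base = rng.normal(size=100)
        m = np.column_stack([base, base, rng.normal(size=100)])
        corr, Z = correlation_cluster(m)
        assert corr.iloc[0, 1] == pytest.approx(1.0)
        assert set(Z[0, :2].astype(int)) == {0, 1}

    def test_reversed_ranks_give_minus_one(self):
        x = np.arange(50, dtype=float)
        m = np.column_stack([x, x[::-1]])
        corr, _ = correlation_cluster(m)
        assert corr.iloc[0, 1] == pytest.approx(-1.0)

    def test_two_planted_groups_recovered(self):
        rng = np.random.default_rng(12)
        sig1, sig2 = rng.normal(size=200), rng.normal(size=200)
        cols = [sig1 + rng.normal(0, 0.3, 200) for _ in range(2)]
        cols += [sig2 + rng.normal(0, 0.3, 200) for _ in range(2)]
        _, Z = correlation_cluster(np.column_stack(cols), method="average")
        labels = cut_two_groups(Z, 4)
        assert labels[0] == labels[1] and labels[2] == labels[3]
        assert labels[0] != labels[2]

    def test_constant_feature_dropped_under_zscaling(self):
        m = np.array([[1.0, 1.0, 1.0], [0.0, 1.0, 2.0]])
        scaled, kept = zscale_rows(m)
        assert list(kept) == [1]
        assert scaled.shape == (1, 3)
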