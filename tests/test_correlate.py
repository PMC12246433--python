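"""Spearman engine, block summaries, coefficient-group tests and PCA."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import endomir as em
from endomir.correlate import block_stats, correlation_matrix
from endomir.errors import ContractError

from conftest import spearman_oracle


def _s(vals, index=None):
    return pd.Series(vals, index=index or [f"m{i}" for i in range(len(vals))], dtype=float)


class TestSpearman:
    def test_monotone_scaling_gives_rho_one(self):
        x = _s([1.0, 2.0, 3.0, 4.0])
        res = em.spearman(x, 2 * x)
        assert res.rho == pytest.approx(1.0)

    def test_reversed_order_gives_minus_one(self):
        x = _s([1.0, 2.0, 3.0, 4.0])
        res = em.spearman(x, _s([4.0, 3.0, 2.0, 1.0]))
        assert res.rho == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        # x=(1,2,3,4), y=(1,3,2,4): ranks equal values; Pearson on ranks is
        # covariance 4 over variances 5 -> 0.8
        res = em.spearman(_s([1, 2, 3, 4]), _s([1, 3, 2, 4]))
        assert res.rho == pytest.approx(0.8, abs=1e-12)

    def test_exact_p_matches_enumeration(self):
        x = _s([1, 2, 3, 4])
        y = _s([1, 3, 2, 4])
        res = em.spearman(x, y, p_method="exact")
        # oracle: enumerate all 24 permutations of y
        obs = spearman_oracle(x.tolist(), y.tolist())
        count = 0
        vals = y.tolist()
        for perm in itertools.permutations(vals):
            if abs(spearman_oracle(x.tolist(), list(perm))) >= abs(obs) - 1e-12:
                count += 1
        assert res.p_value == pytest.approx(count / math.factorial(4))

    def test_union_policy_fills_absent_mirnas_with_zero(self):
        x = pd.Series({"a": 0.5, "b": 0.5})
        y = pd.Series({"b": 0.4, "c": 0.6})
        res = em.spearman(x, y, policy="union")
        assert res.n == 3
        oracle = spearman_oracle([0.5, 0.5, 0.0], [0.0, 0.4, 0.6])
        assert res.rho == pytest.approx(oracle, abs=1e-12)

    def test_intersection_policy_restricts_to_shared_support(self):
        x = pd.Series({"a": 0.2, "b": 0.3, "c": 0.5, "d": 0.1})
        y = pd.Series({"b": 0.1, "c": 0.2, "d": 0.7, "e": 0.4})
        res = em.spearman(x, y, policy="intersection")
        assert res.n == 3  # b, c, d

    def test_too_few_observations_rejected(self):
        with pytest.raises(ContractError, match=">= 3"):
            em.spearman(_s([1, 2]), _s([2, 3]))

    def test_zero_rank_variance_reports_nan(self):
        res = em.spearman(_s([1.0, 1.0, 1.0]), _s([1, 2, 3]))
        assert np.isnan(res.rho)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.01, 100.0), min_size=4, max_size=12, unique=True))
    def test_invariance_under_strictly_increasing_transform(self, vals):
        rng = np.random.default_rng(42)
        y = _s(list(rng.permutation(len(vals)) + 1.0))
        x = _s(vals)
        r1 = em.spearman(x, y, p_method="none").rho
        r2 = em.spearman(np.log(x) * 3 + 5, y, p_method="none").rho
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_matches_bruteforce_on_random_vectors_with_ties(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = int(rng.integers(11, 30))
            x = rng.integers(0, 8, n).astype(float)  # ties likely
            y = rng.normal(size=n)
            if np.unique(x).size < 2:
                continue
            res = em.spearman(_s(list(x)), _s(list(y)), p_method="approx")
            assert res.rho == pytest.approx(spearman_oracle(x, y), abs=1e-12)


class TestCorrelationMatrix:
    def test_identical_signatures_off_diagonal_one(self):
        df = pd.DataFrame({"a": [0.2, 0.3, 0.5], "b": [0.2, 0.3, 0.5]})
        s = correlation_matrix(df)
        assert s.rho.loc["a", "b"] == pytest.approx(1.0)

    def test_symmetry_and_unit_diagonal(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.dirichlet(np.ones(30), size=5).T, columns=list("abcde"))
        s = correlation_matrix(df)
        assert np.allclose(s.rho.values, s.rho.values.T, atol=1e-12)
        assert np.allclose(np.diag(s.rho.values), 1.0)

    def test_three_signatures_have_three_unique_pairs(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.dirichlet(np.ones(20), size=3).T, columns=list("abc"))
        s = block_stats(correlation_matrix(df), {c: "g" for c in "abc"}, [("g", "g")])
        assert s.blocks[("g", "g")].n_pairs == 3


class TestBlockStats:
    def test_uniform_off_diagonal_block(self):
        rho = pd.DataFrame(0.5, index=list("abc"), columns=list("abc"))
        np.fill_diagonal(rho.values, 1.0)
        s = em.correlate.BlockSummary(rho=rho, n=rho * 0, policy="union")
        out = block_stats(s, {c: "g" for c in "abc"}, [("g", "g")])
        st_ = out.blocks[("g", "g")]
        assert st_.mean == 0.5 and st_.sd == 0.0 and st_.n_pairs == 3

    def test_single_pair_cross_block(self):
        rho = pd.DataFrame([[1.0, 0.7], [0.7, 1.0]], index=["a", "b"], columns=["a", "b"])
        s = em.correlate.BlockSummary(rho=rho, n=rho * 0, policy="union")
        out = block_stats(s, {"a": "g1", "b": "g2"}, [("g1", "g2")])
        assert out.blocks[("g1", "g2")].n_pairs == 1
        assert out.blocks[("g1", "g2")].sd == 0.0

    def test_empty_block_is_an_error(self):
        rho = pd.DataFrame([[1.0]], index=["a"], columns=["a"])
        s = em.correlate.BlockSummary(rho=rho, n=rho * 0, policy="union")
        with pytest.raises(ContractError, match="g2"):
            block_stats(s, {"a": "g1"}, [("g1", "g2")])


class TestCompareCoefficientGroups:
    def test_identical_groups_give_t_zero_p_one(self):
        res = em.compare_coefficient_groups([0.5, 0.6], [0.5, 0.6], test="student_t")
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_separated_groups_give_small_p_with_direction(self):
        res = em.compare_coefficient_groups([0.1, 0.2], [0.8, 0.9], test="student_t")
        assert res.p_value < 0.05
        assert res.mean_a < res.mean_b

    @pytest.mark.parametrize("na,nb", [(3, 3), (4, 5), (6, 6), (2, 6)])
    def test_mann_whitney_matches_exact_enumeration(self, na, nb):
        rng = np.random.default_rng(na * 10 + nb)
        a = rng.normal(size=na)
        b = rng.normal(0.5, size=nb)
        res = em.compare_coefficient_groups(a, b, test="mann_whitney")
        # oracle: enumerate all C(na+nb, na) assignments of the pooled values
        pooled = np.concatenate([a, b])
        idx = range(na + nb)

        def u_stat(ia):
            av = pooled[list(ia)]
            bv = pooled[[i for i in idx if i not in set(ia)]]
            return sum((x > y) + 0.5 * (x == y) for x in av for y in bv)

        u_obs = u_stat(range(na))
        us = [u_stat(c) for c in itertools.combinations(idx, na)]
        mu = na * nb / 2
        p_exact = sum(abs(u - mu) >= abs(u_obs - mu) - 1e-12 for u in us) / len(us)
        assert res.p_value == pytest.approx(p_exact, abs=1e-12)

    def test_unknown_test_rejected(self):
        with pytest.raises(ContractError):
            em.compare_coefficient_groups([0.1], [0.2], test="anova")


class TestPCA:
    def test_duplicated_sample_gets_identical_scores(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.dirichlet(np.ones(20), size=4).T, columns=list("abcd"))
        df["e"] = df["a"]
        res = em.pca(df)
        np.testing.assert_allclose(
            res.scores.loc["a"].values, res.scores.loc["e"].values, atol=1e-10
        )

    def test_collinear_samples_put_all_variance_on_pc1(self):
        base = np.array([0.5, 0.3, 0.2])
        df = pd.DataFrame(
            {"a": base, "b": base * 2, "c": base * 3.5}, index=["m1", "m2", "m3"]
        )
        res = em.pca(df)
        assert res.explained_ratio[0] == pytest.approx(1.0, abs=1e-12)

    def test_variance_decomposition_identity(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.normal(size=(25, 6)), columns=list("abcdef"))
        res = em.pca(df)
        X = df.T.to_numpy()
        Xc = X - X.mean(axis=0, keepdims=True)
        total = (Xc**2).sum() / (X.shape[0] - 1)
        assert res.explained_variance.sum() == pytest.approx(total, rel=1e-10)
        # non-increasing, nonnegative
        assert np.all(np.diff(res.explained_variance) <= 1e-12)
        assert np.all(res.explained_variance >= 0)

    def test_loadings_are_orthogonal(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.normal(size=(15, 5)), columns=list("abcde"))
        res = em.pca(df)
        L = res.loadings.to_numpy()
        np.testing.assert_allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-10)

    def test_constant_matrix_has_zero_variance(self):
        df = pd.DataFrame(0.25, index=[f"m{i}" for i in range(4)], columns=list("abc"))
        res = em.pca(df)
        assert np.allclose(res.explained_variance, 0.0)
        assert np.allclose(res.scores.values, 0.0, atol=1e-12)
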