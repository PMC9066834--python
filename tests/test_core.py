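"""Rubin's-rule pooling and the selection algebra."""

import numpy as np
import pytest
from scipy import stats

from rrbart.core import (
    PooledScore,
    VIPDistribution,
    average_vip,
    distance_scores,
    median_baseline_select,
    min_vip_gate,
    pooled_posterior_select,
    rubins_pool,
    select,
    select_from_vip,
)

from conftest import random_vip_array


def pool_bruteforce(delta, n, alpha=0.05):
    """Literal loop-wise transcription of the pooling formulas, kept
    independent of the vectorized implementation."""
    K, M, P = delta.shape
    out = []
    for k in range(K):
        dbar_m = [sum(delta[k, m, p] for p in range(P)) / P for m in range(M)]
        qbar = sum(dbar_m) / M
        # within: variance among the P draws of each imputation, divided by n
        w = 0.0
        for m in range(M):
            mean_m = dbar_m[m]
            var_m = sum((delta[k, m, p] - mean_m) ** 2 for p in range(P)) / (P - 1)
            w += var_m / n
        w /= M
        b = sum((dbar_m[m] - qbar) ** 2 for m in range(M)) / (M - 1)
        t = w + (1.0 + 1.0 / M) * b
        if b == 0.0:
            df = np.inf
            crit = stats.norm.ppf(1 - alpha / 2)
        else:
            df = (M - 1) / ((b + b / M) / t) ** 2
            crit = stats.t.ppf(1 - alpha / 2, df)
        half = 0.0 if t == 0.0 else crit * np.sqrt(t)
        out.append((qbar, w, b, t, df, qbar - half, qbar + half))
    return np.array(out)


class TestRubinsPool:
    def test_matches_bruteforce_on_fuzzed_arrays(self):
        rng = np.random.default_rng(1234)
        for case in range(100):
            K = int(rng.integers(1, 4))
            M = int(rng.integers(2, 5))
            P = int(rng.integers(2, 6))
            n = int(rng.integers(5, 200))
            delta = rng.normal(0.0, 0.1, size=(K, M, P))
            got = rubins_pool(delta, n=n)
            want = pool_bruteforce(delta, n=n)
            np.testing.assert_allclose(got.qbar, want[:, 0], atol=1e-12)
            np.testing.assert_allclose(got.within, want[:, 1], atol=1e-12)
            np.testing.assert_allclose(got.between, want[:, 2], atol=1e-12)
            np.testing.assert_allclose(got.total, want[:, 3], atol=1e-12)
            np.testing.assert_allclose(got.df, want[:, 4], atol=1e-12)
            np.testing.assert_allclose(got.ci_lo, want[:, 5], atol=1e-12)
            np.testing.assert_allclose(got.ci_hi, want[:, 6], atol=1e-12)

    def test_hand_example(self):
        # K=1, M=2, P=3, n=10 — values frozen from the brute-force oracle
        delta = np.array([[[0.1, 0.2, 0.3], [0.2, 0.3, 0.4]]])
        want = pool_bruteforce(delta, n=10)
        got = rubins_pool(delta, n=10)
        assert got.qbar[0] == pytest.approx(0.25, abs=1e-15)
        assert got.between[0] == pytest.approx(0.005, abs=1e-15)
        np.testing.assert_allclose(
            [got.within[0], got.total[0], got.df[0]],
            [want[0, 1], want[0, 3], want[0, 4]], atol=1e-12)

    def test_constant_delta_degenerate(self):
        delta = np.full((2, 3, 4), 0.7)
        got = rubins_pool(delta, n=50)
        np.testing.assert_allclose(got.qbar, 0.7)
        np.testing.assert_allclose(got.within, 0.0, atol=1e-15)
        np.testing.assert_allclose(got.between, 0.0, atol=1e-15)
        np.testing.assert_allclose(got.total, 0.0, atol=1e-15)
        np.testing.assert_allclose(got.ci_lo, 0.7, atol=1e-7)
        np.testing.assert_allclose(got.ci_hi, 0.7, atol=1e-7)

    def test_total_variance_identity(self):
        rng = np.random.default_rng(7)
        delta = rng.normal(size=(4, 5, 6))
        got = rubins_pool(delta, n=100)
        np.testing.assert_allclose(
            got.total, got.within + (1 + 1 / 5) * got.between, rtol=0, atol=0)

    def test_zero_between_variance_uses_normal_quantile(self):
        # identical draws across imputations, varying within -> B = 0
        base = np.array([0.1, 0.2, 0.3, 0.4])
        delta = np.tile(base, (1, 3, 1)).reshape(1, 3, 4)
        got = rubins_pool(delta, n=10, alpha=0.05)
        assert np.isinf(got.df[0])
        half = stats.norm.ppf(0.975) * np.sqrt(got.total[0])
        assert got.ci_hi[0] - got.qbar[0] == pytest.approx(half, rel=1e-12)

    def test_m1_rejected(self):
        with pytest.raises(ValueError, match="M >= 2"):
            rubins_pool(np.zeros((2, 1, 5)), n=10)

    def test_mcse_within_mode_divides_by_draws(self):
        rng = np.random.default_rng(3)
        delta = rng.normal(size=(2, 3, 8))
        paper = rubins_pool(delta, n=100, within_var="paper")
        mcse = rubins_pool(delta, n=100, within_var="mcse")
        np.testing.assert_allclose(mcse.within * 8, paper.within * 100, rtol=1e-12)


class TestVipAlgebra:
    def test_average_vip_constant(self):
        v = VIPDistribution(np.full((5, 2, 3), 0.2))
        np.testing.assert_allclose(average_vip(v), 0.2)

    def test_average_vip_arithmetic(self):
        vip = np.array([[[0.3, 0.5]], [[0.7, 0.5]]])  # K=2, M=1, P=2
        np.testing.assert_allclose(
            average_vip(VIPDistribution(vip)), [0.4, 0.6])

    def test_average_vip_sums_to_one(self):
        rng = np.random.default_rng(11)
        v = VIPDistribution(random_vip_array(rng, 6, 3, 4))
        assert average_vip(v).sum() == pytest.approx(1.0, abs=1e-12)

    def test_gate_triggers_above_half_uniform(self):
        means = np.full(10, 0.1)
        means[3] = 0.08        # the all-useful regime
        gate, k = min_vip_gate(means)
        assert gate and k == 3

    def test_gate_boundary_is_strict(self):
        means = np.full(10, 0.1)
        means[0] = 0.05        # exactly 1/(2K): proceed with selection
        gate, k = min_vip_gate(means)
        assert not gate and k == 0

    def test_never_split_predictor_blocks_gate(self):
        means = np.array([0.5, 0.5, 0.0])
        gate, k = min_vip_gate(means)
        assert not gate and k == 2

    def test_distance_reconstruction(self):
        rng = np.random.default_rng(5)
        v = VIPDistribution(random_vip_array(rng, 4, 2, 3))
        means = average_vip(v)
        delta = distance_scores(v, means.min())
        np.testing.assert_allclose(delta + means.min(), v.vip, atol=0)

    def test_min_predictor_distance_centers_at_zero(self):
        rng = np.random.default_rng(9)
        v = VIPDistribution(random_vip_array(rng, 4, 3, 5))
        means = average_vip(v)
        k = int(np.argmin(means))
        delta = distance_scores(v, means[k])
        assert delta[k].mean() == pytest.approx(0.0, abs=1e-12)

    def test_vip_validation(self):
        with pytest.raises(ValueError, match="sum to 1"):
            VIPDistribution(np.full((2, 2, 2), 0.7))
        with pytest.raises(ValueError, match="K x M x P"):
            VIPDistribution(np.full((2, 2), 0.5))


def _score(lo, hi):
    k = len(lo)
    z = np.zeros(k)
    return PooledScore(qbar=(np.array(lo) + np.array(hi)) / 2, within=z,
                       between=z, total=z + 1e-4, df=z + 10,
                       ci_lo=np.array(lo), ci_hi=np.array(hi),
                       alpha=0.05, M=3, n=100)


class TestSelect:
    def test_ci_rules(self):
        res = select(_score([0.01, -0.01, 0.00], [0.05, 0.02, 0.02]),
                     names=["a", "b", "c"])
        # positive interval selected; spanning zero not; touching zero not
        assert res.selected == ["a"]

    def test_alpha_monotonicity(self):
        rng = np.random.default_rng(21)
        vip = random_vip_array(rng, 6, 4, 10)
        v = VIPDistribution(vip)
        sets = {}
        for alpha in (0.01, 0.05, 0.10):
            sets[alpha] = set(select_from_vip(v, n=200, alpha=alpha).selected)
        assert sets[0.01] <= sets[0.05] <= sets[0.10]

    def test_gate_path_returns_all(self):
        vip = np.full((5, 3, 4), 0.2)   # flat: min mean 0.2 > 0.1
        res = select_from_vip(VIPDistribution(vip), n=100)
        assert res.gate_triggered
        assert res.selected == res.names


class TestBaselines:
    def test_median_rule_half_selected(self):
        vip = np.zeros((4, 1, 1))
        vip[:, 0, 0] = [0.4, 0.3, 0.2, 0.1]
        v = VIPDistribution(vip)
        assert median_baseline_select(v, names=list("abcd")) == ["a", "b"]

    def test_median_rule_all_equal_selects_none(self):
        v = VIPDistribution(np.full((4, 1, 2), 0.25))
        assert median_baseline_select(v) == []

    def test_pooled_posterior_agrees_on_degenerate(self):
        vip = np.zeros((2, 2, 3))
        vip[0] = 0.9
        vip[1] = 0.1
        v = VIPDistribution(vip)
        pooled = select_from_vip(v, n=100)
        alt = pooled_posterior_select(v)
        assert set(alt) == set(pooled.selected) == {"X1"}

    def test_pooled_posterior_close_to_rubin_on_simulated(self):
        rng = np.random.default_rng(33)
        agree = total = 0
        for _ in range(20):
            base = np.array([0.3, 0.25, 0.15, 0.1, 0.1, 0.1])
            vip = base[:, None, None] + rng.normal(0, 0.02, (6, 4, 30))
            vip = np.clip(vip, 1e-4, None)
            vip /= vip.sum(axis=0, keepdims=True)
            v = VIPDistribution(vip)
            r = set(select_from_vip(v, n=500).selected)
            p = set(pooled_posterior_select(v))
            for name in v.names or [f"X{i+1}" for i in range(6)]:
                agree += (name in r) == (name in p)
                total += 1
        assert agree / total >= 0.9
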