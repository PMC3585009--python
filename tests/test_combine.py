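"""Tests for the gene-level P-value combiners and the adaptive sampler."""
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gggtest.combine import (
    chunk_pairs,
    empirical_p,
    gg_gates,
    gg_minp,
    gg_tprod,
    gg_tts,
    log_tprod_statistic,
    tprod_statistic,
    tts_statistic,
)
from gggtest.correlation import SigmaMatrix
from gggtest.datatypes import TruncationConfig


def sigma(V):
    q = V.shape[0]
    return SigmaMatrix(values=V, source="genotypes",
                       pair_index=[(i, 0) for i in range(q)])


def random_correlation(q, rng):
    A = rng.standard_normal((q, q + 5))
    C = np.corrcoef(A)
    return C


class TestMinP:
    def test_single_p_reduces_to_marker_test(self):
        res = gg_minp([0.037], sigma(np.eye(1)))
        assert res.p_gene == pytest.approx(0.037)

    def test_independent_tests_match_sidak(self):
        """Sigma = I: gene P = 1 - (1 - Pmin)^m (m=10, p=0.01 -> 0.09562)."""
        p = np.full(10, 0.5)
        p[3] = 0.01
        res = gg_minp(p, sigma(np.eye(10)), n_qmc=8192, n_shifts=4)
        assert res.p_gene == pytest.approx(1 - 0.99**10, abs=1e-3)
        assert res.p_gene == pytest.approx(0.09562, abs=1e-3)

    def test_total_correlation_reduces_to_pmin(self):
        V = np.ones((6, 6))
        res = gg_minp(np.full(6, 0.02), sigma(V))
        assert res.p_gene == pytest.approx(0.02, abs=1e-4)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            gg_minp([0.1, 0.2], sigma(np.eye(3)))

    def test_seeded_reproducibility(self, rng):
        V = random_correlation(8, rng)
        p = rng.uniform(0.001, 1, 8)
        a = gg_minp(p, sigma(V), seed=7)
        b = gg_minp(p, sigma(V), seed=7)
        assert a.p_gene == b.p_gene


class TestGates:
    def test_identity_sigma_is_simes(self):
        res = gg_gates([0.01, 0.02, 0.9], sigma(np.eye(3)))
        assert res.p_gene == pytest.approx(0.03)

    def test_total_correlation_is_pmin(self):
        V = np.ones((4, 4))
        res = gg_gates([0.3, 0.1, 0.4, 0.2], sigma(V))
        assert res.p_gene == pytest.approx(0.1)

    def test_against_brute_force_prefix_maxima(self, rng):
        """Random Sigma (q=6) vs a naive double-loop reference."""
        for _ in range(10):
            V = random_correlation(6, rng)
            p = rng.uniform(1e-4, 1, 6)
            res = gg_gates(p, sigma(V))
            order = np.argsort(p)
            ps = p[order]
            R = V[np.ix_(order, order)]
            me = []
            for j in range(1, 7):
                count = 1.0
                for i in range(1, j):
                    rho2 = max(R[i, l] ** 2 for l in range(i))
                    count += math.sqrt(1 - min(rho2, 1.0))
                me.append(count)
            expected = min(1.0, min(me[-1] * ps[j] / me[j] for j in range(6)))
            assert res.p_gene == pytest.approx(expected, rel=1e-12)

    def test_monotone_in_each_p(self, rng):
        V = random_correlation(5, rng)
        p = rng.uniform(0.05, 1, 5)
        base = gg_gates(p, sigma(V)).p_gene
        for k in range(5):
            q = p.copy()
            q[k] *= 0.5
            assert gg_gates(q, sigma(V)).p_gene <= base + 1e-12


class TestTruncatedStatistics:
    def test_tts_empty_truncation_set(self):
        assert tts_statistic([0.2, 0.9, 0.06], tau=0.05) == 0.0

    def test_tts_single_p(self):
        assert tts_statistic([0.01], tau=0.05) == pytest.approx(0.98)

    def test_tts_matches_independent_formula(self, rng):
        """Second implementation straight from the tail-strength definition."""
        p = rng.uniform(0, 0.4, 20)
        m = 20
        ps = sorted(p)
        expected = sum(
            1 - ps[j] * (m + 1) / (j + 1) for j in range(m) if ps[j] <= 0.05
        )
        assert tts_statistic(p, 0.05) == pytest.approx(expected, rel=1e-12)

    def test_tts_monotone_under_p_decrease(self, rng):
        p = rng.uniform(0.001, 1, 15)
        base = tts_statistic(p, 0.05)
        for k in range(15):
            q = p.copy()
            q[k] *= 0.1
            assert tts_statistic(q, 0.05) >= base - 1e-12

    def test_tprod_examples(self):
        assert tprod_statistic([0.2, 0.9], tau=0.05) == 1.0
        assert tprod_statistic([0.01, 0.04, 0.5], tau=0.05) == pytest.approx(4e-4)

    def test_tprod_log_identity(self, rng):
        p = rng.uniform(0, 1, 30)
        qualifying = p[p <= 0.05]
        assert log_tprod_statistic(p, 0.05) == pytest.approx(
            np.sum(np.log(qualifying)) if qualifying.size else 0.0
        )

    def test_invalid_tau(self):
        with pytest.raises(ValueError):
            tts_statistic([0.5], tau=1.5)


class TestEmpiricalP:
    def test_tprod_of_one_gives_p_one(self):
        """Every null draw has product <= 1: ties count, so p = 1."""
        res = gg_tprod(
            np.array([0.6, 0.7]), sigma(np.eye(2)),
            TruncationConfig(stages=(2000,), thresholds=()), seed=1,
        )
        assert res.statistic == 1.0
        assert res.p_gene == 1.0

    def test_tts_of_zero_is_not_significant(self):
        res = gg_tts(
            np.array([0.6, 0.7]), sigma(np.eye(2)),
            TruncationConfig(stages=(2000,), thresholds=()), seed=1,
        )
        assert res.statistic == 0.0
        assert res.p_gene > 0.5

    def test_closed_form_product_of_two_uniforms(self):
        """Independent m=2, no truncation: Pr(U1*U2 <= w) = w(1 - ln w)."""
        w = 0.05
        p_emp, n_draws = empirical_p(
            math.log(w),
            lambda P: np.log(P).sum(axis=1),
            sigma(np.eye(2)),
            config=TruncationConfig(stages=(100_000,), thresholds=()),
            seed=3,
            larger_is_significant=False,
        )
        exact = w * (1 - math.log(w))
        assert n_draws == 100_000
        assert abs(p_emp - exact) < 3 * math.sqrt(exact * (1 - exact) / n_draws)

    def test_reproducible_and_stable(self, rng):
        V = random_correlation(6, rng)
        p = rng.uniform(0.001, 0.5, 6)
        cfg = TruncationConfig(stages=(4000,), thresholds=())
        a = gg_tts(p, sigma(V), cfg, seed=11)
        b = gg_tts(p, sigma(V), cfg, seed=11)
        assert a.p_gene == b.p_gene
        assert a.n_null_samples == 4000
        # doubling the draws moves the estimate < 3 binomial SEs
        c = gg_tts(p, sigma(V), TruncationConfig(stages=(8000,), thresholds=()), seed=11)
        se = math.sqrt(max(a.p_gene, 1 / 4000) * (1 - a.p_gene) / 4000)
        assert abs(c.p_gene - a.p_gene) <= 3 * se + 1e-12

    def test_adaptive_escalation_records_draws(self, rng):
        """A strong observed signal escalates past stage 1."""
        V = np.eye(4)
        p = np.array([1e-6, 2e-6, 0.5, 0.9])
        cfg = TruncationConfig(stages=(1000, 9000), thresholds=(0.01,))
        res = gg_tprod(p, sigma(V), cfg, seed=5)
        assert res.n_null_samples == 10_000
        assert res.p_gene == pytest.approx(1 / 10_000)  # floored at 1/draws

    def test_default_config_ceiling_and_floor(self):
        cfg = TruncationConfig()
        assert cfg.max_draws == 10**8
        assert 1 / cfg.max_draws == 1e-8
        assert cfg.tau == 0.05

    def test_bad_config(self):
        with pytest.raises(ValueError):
            TruncationConfig(stages=(0, 100), thresholds=(0.01,))
        with pytest.raises(ValueError):
            TruncationConfig(tau=1.5)


class TestChunking:
    def test_small_grid_single_chunk(self):
        assert chunk_pairs(10, 20) == [(range(10), range(20))]

    @given(st.integers(1, 80), st.integers(1, 80))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_partition_property(self, m1, m2):
        chunks = chunk_pairs(m1, m2, max_pairs=500)
        seen = set()
        for r1, r2 in chunks:
            assert len(r1) * len(r2) <= 500
            for i in r1:
                for j in r2:
                    assert (i, j) not in seen
                    seen.add((i, j))
        assert len(seen) == m1 * m2

    def test_large_grid_bounds(self):
        chunks = chunk_pairs(30, 40, max_pairs=500)
        assert len(chunks) >= 3
        assert all(len(r1) * len(r2) <= 500 for r1, r2 in chunks)

    def test_boundary_501(self):
        chunks = chunk_pairs(1, 501, max_pairs=500)
        sizes = sorted(len(r1) * len(r2) for r1, r2 in chunks)
        assert sizes == [1, 500]
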