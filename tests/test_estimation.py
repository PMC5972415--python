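"""Estimator checks: likelihood oracle, fits, bias correction and the
LD measures."""

import numpy as np
import pytest

from gusld.estimation import (
    MISSING,
    LDParams,
    MonomorphicLocusError,
    PairCounts,
    _multistart_points,
    _unpack,
    bias_correct,
    d_prime,
    fit_gusld,
    fit_standard,
    genotype_table,
    naive_genotype_call,
    naive_genotype_calls,
    pair_log_likelihood,
    pairwise_ld,
    r_squared,
)
from gusld.simulate import SimConfig, simulate_pair

from conftest import random_valid_params
from oracles import brute_force_loglik, em_ld_estimates


def random_counts(rng, n, dmax):
    d1 = rng.integers(0, dmax + 1, n)
    d2 = rng.integers(0, dmax + 1, n)
    y1 = rng.binomial(d1, rng.uniform(0.2, 0.8))
    y2 = rng.binomial(d2, rng.uniform(0.2, 0.8))
    return PairCounts(y1, d1, y2, d2)


def table_to_calls(table):
    """Expand a 3x3 count table into per-individual call code arrays."""
    g1, g2 = [], []
    for a in range(3):
        for b in range(3):
            g1 += [a] * int(table[a][b])
            g2 += [b] * int(table[a][b])
    return np.array(g1), np.array(g2)


class TestPairLogLikelihood:
    def test_single_informative_individual(self):
        # one read of each allele... er, one ref read per locus; second
        # individual unsequenced so it contributes nothing
        c = PairCounts([1, 0], [1, 0], [1, 0], [1, 0])
        assert pair_log_likelihood(c, LDParams(0.5, 0.5, 0.0, 0.0)) == pytest.approx(
            np.log(0.25), abs=1e-12
        )
        assert pair_log_likelihood(c, LDParams(0.5, 0.5, 0.25, 0.0)) == pytest.approx(
            np.log(0.375), abs=1e-12
        )

    def test_no_data_gives_zero(self):
        c = PairCounts([0, 0], [0, 0], [0, 0], [0, 0])
        assert pair_log_likelihood(c, LDParams(0.3, 0.8, 0.02, 0.05)) == 0.0

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(60):
            n = int(rng.integers(2, 21))
            counts = random_counts(rng, n, dmax=6)
            p1, p2, D, eps = random_valid_params(rng)
            got = pair_log_likelihood(counts, LDParams(p1, p2, D, eps))
            want = brute_force_loglik(
                counts.y1, counts.d1, counts.y2, counts.d2, p1, p2, D, eps
            )
            assert got == pytest.approx(want, abs=1e-12)


class TestNaiveCalls:
    @pytest.mark.parametrize("y,d,expected", [
        (2, 2, "AA"), (1, 2, "AB"), (0, 2, "BB"), (0, 0, "missing"), (3, 7, "AB"),
    ])
    def test_scalar(self, y, d, expected):
        assert naive_genotype_call(y, d) == expected

    def test_scalar_domain_error(self):
        with pytest.raises(ValueError):
            naive_genotype_call(3, 2)

    def test_vectorized_matches_scalar(self, rng):
        d = rng.integers(0, 5, 200)
        y = rng.binomial(d, 0.5)
        codes = naive_genotype_calls(y, d)
        names = ["AA", "AB", "BB"]
        for yi, di, ci in zip(y, d, codes):
            want = naive_genotype_call(int(yi), int(di))
            assert (names[ci] if ci != MISSING else "missing") == want


class TestMeasures:
    def test_bias_correction_arithmetic(self):
        assert bias_correct(0.1, 100, 0.5, 0.5) == pytest.approx(0.1 * 200 / 199)
        assert bias_correct(0.25, 100, 0.5, 0.5) == 0.25  # clamped at Dmax
        assert bias_correct(0.0, 7, 0.3, 0.8) == 0.0

    @pytest.mark.parametrize("D,p1,p2,expected", [
        (0.25, 0.5, 0.5, 1.0),
        (0.0, 0.3, 0.8, 0.0),
        (-0.05, 0.5, 0.75, -0.4),
    ])
    def test_d_prime(self, D, p1, p2, expected):
        assert d_prime(D, p1, p2) == pytest.approx(expected)

    @pytest.mark.parametrize("D,p1,p2,expected", [
        (0.25, 0.5, 0.5, 1.0),
        (0.0, 0.4, 0.6, 0.0),
        (0.1, 0.5, 0.75, 0.1**2 / (0.25 * 0.1875)),
    ])
    def test_r_squared(self, D, p1, p2, expected):
        assert r_squared(D, p1, p2) == pytest.approx(expected)

    def test_monomorphic_rejected(self):
        with pytest.raises(Exception):
            d_prime(0.1, 1.0, 0.5)
        with pytest.raises(Exception):
            r_squared(0.1, 0.0, 0.5)

    def test_relabel_invariance(self, rng):
        """r2 and |D'| are invariant to swapping ref/alt at one locus."""
        for _ in range(30):
            p1, p2, D, _ = random_valid_params(rng)
            assert r_squared(D, p1, p2) == pytest.approx(
                r_squared(-D, 1 - p1, p2), abs=1e-12
            )
            assert abs(d_prime(D, p1, p2)) == pytest.approx(
                abs(d_prime(-D, 1 - p1, p2)), abs=1e-12
            )


class TestFitGusld:
    def test_recovers_truth_at_high_information(self):
        cfg = SimConfig(n=2000, pA1=0.5, pA2=0.5, D=0.15, eps=0.01,
                        mu1=15, mu2=15, seed=7)
        counts, _ = simulate_pair(cfg)
        est = fit_gusld(counts)
        assert est.converged
        # well within Monte-Carlo uncertainty at this n and depth
        assert est.D_hat == pytest.approx(0.15, abs=0.02)
        assert est.pA1_hat == pytest.approx(0.5, abs=0.03)
        assert est.eps_hat == pytest.approx(0.01, abs=0.01)

    def test_monomorphic_locus_raises(self):
        counts = PairCounts([2, 3, 1], [2, 3, 1], [1, 2, 0], [2, 3, 1])
        with pytest.raises(MonomorphicLocusError, match="locus 1"):
            fit_gusld(counts)

    def test_estimate_respects_constraints(self, rng):
        from gusld.model import d_bounds

        for seed in range(5):
            cfg = SimConfig(n=50, pA1=0.3, pA2=0.7, D=0.05, eps=0.01,
                            mu1=2, mu2=2, seed=seed)
            counts, _ = simulate_pair(cfg)
            est = fit_gusld(counts)
            dmin, dmax = d_bounds(est.pA1_hat, est.pA2_hat)
            assert dmin - 1e-9 <= est.D_hat <= dmax + 1e-9
            assert -1 <= est.d_prime <= 1
            assert 0 <= est.r2 <= 1
            assert est.n_used == counts.n_used

    def test_fitted_loglik_beats_every_start(self):
        cfg = SimConfig(n=100, pA1=0.5, pA2=0.5, D=0.1, eps=0.01,
                        mu1=3, mu2=3, seed=11)
        counts, _ = simulate_pair(cfg)
        est = fit_gusld(counts)
        p0_1 = counts.y1.sum() / counts.d1.sum()
        p0_2 = counts.y2.sum() / counts.d2.sum()
        for x0 in _multistart_points(p0_1, p0_2, with_eps=True):
            start_ll = pair_log_likelihood(counts, LDParams(*_unpack(x0, None)))
            assert est.loglik >= start_ll - 1e-9

    def test_fix_eps_zero_reproduces_error_free_model(self):
        cfg = SimConfig(n=500, pA1=0.5, pA2=0.5, D=0.1, eps=0.0,
                        mu1=30, mu2=30, seed=3)
        counts, _ = simulate_pair(cfg)
        est = fit_gusld(counts, fix_eps=0.0)
        assert est.eps_hat == 0.0
        assert est.D_hat == pytest.approx(0.1, abs=0.03)

    def test_deterministic(self):
        cfg = SimConfig(n=80, pA1=0.4, pA2=0.6, D=0.05, eps=0.01,
                        mu1=2, mu2=2, seed=9)
        counts, _ = simulate_pair(cfg)
        a, b = fit_gusld(counts), fit_gusld(counts)
        assert a == b


class TestFitStandard:
    def test_perfect_coupling_hits_boundary(self):
        table = [[25, 0, 0], [0, 0, 0], [0, 0, 25]]
        est = fit_standard(*table_to_calls(table))
        assert est.D_raw == pytest.approx(0.25, abs=1e-6)
        assert est.D_hat == 0.25  # snapped to the boundary exactly
        assert est.d_prime == 1.0

    def test_factorized_table_gives_zero_d(self):
        # outer product of margins (1,2,1)x(1,2,1) scaled by 4
        table = [[4, 8, 4], [8, 16, 8], [4, 8, 4]]
        est = fit_standard(*table_to_calls(table))
        assert est.D_raw == pytest.approx(0.0, abs=1e-7)

    def test_matches_em_oracle_on_fixed_table(self):
        table = np.array([[20, 10, 2], [10, 20, 10], [2, 10, 16]])
        est = fit_standard(*table_to_calls(table))
        oracle = em_ld_estimates(table)
        assert est.D_raw == pytest.approx(oracle["D"], abs=1e-6)
        assert est.pA1_hat == pytest.approx(oracle["p1"], abs=1e-6)
        assert est.pA2_hat == pytest.approx(oracle["p2"], abs=1e-6)

    def test_missing_calls_excluded(self):
        g1 = np.array([0, 0, 1, 1, 2, MISSING, 0])
        g2 = np.array([0, 1, 1, 2, 2, 0, MISSING])
        assert genotype_table(g1, g2).sum() == 5
        est = fit_standard(g1, g2)
        assert est.n_used == 5
        assert est.eps_hat is None

    def test_monomorphic_calls_raise(self):
        g1 = np.zeros(20, dtype=int)  # every call AA at locus 1
        g2 = np.tile([0, 1, 2, 1], 5)
        with pytest.raises(MonomorphicLocusError, match="locus 1"):
            fit_standard(g1, g2)


class TestPairwiseLD:
    def _matrix(self, seed=0, n=60, L=3, mu=4.0):
        rng = np.random.default_rng(seed)
        y = np.empty((n, L), dtype=int)
        d = np.empty((n, L), dtype=int)
        for j in range(L):
            cfg = SimConfig(n=n, pA1=0.5, pA2=0.5, D=0.1, eps=0.01,
                            mu1=mu, mu2=mu)
            counts, _ = simulate_pair(cfg, rng=rng)
            y[:, j], d[:, j] = counts.y1, counts.d1
        return y, d

    def test_row_count_is_all_pairs(self):
        y, d = self._matrix(L=3)
        res = pairwise_ld(y, d, method="gusld")
        assert len(res) == 3
        res = pairwise_ld(y, d, method="standard")
        assert len(res) == 3

    def test_duplicated_locus_has_full_ld(self):
        # high depth so genotypes are effectively known; a locus paired
        # with itself then sits on the coupling boundary (r2 = 1)
        y, d = self._matrix(L=2, mu=20.0, n=100)
        y[:, 1], d[:, 1] = y[:, 0], d[:, 0]
        res = pairwise_ld(y, d, method="gusld", fix_eps=0.0)
        assert res["r2"].iloc[0] == pytest.approx(1.0, abs=0.01)

    def test_large_panel_pair_count(self):
        # 38 loci -> 703 unordered pairs; all-zero depths keep this a
        # pure bookkeeping check (every pair reports insufficient_overlap)
        y = np.zeros((10, 38), dtype=int)
        d = np.zeros((10, 38), dtype=int)
        res = pairwise_ld(y, d, method="gusld")
        assert len(res) == 703
        assert (res["status"] == "insufficient_overlap").all()

    def test_failures_reported_not_dropped(self):
        y, d = self._matrix(L=3)
        y[:, 2] = d[:, 2]  # locus 3 monomorphic: all reads reference
        res = pairwise_ld(y, d, method="gusld")
        assert len(res) == 3
        assert set(res["status"]) == {"ok", "monomorphic"}
        assert (res["status"] == "monomorphic").sum() == 2
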