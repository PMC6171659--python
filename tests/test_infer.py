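"""Rate-matrix construction, propagator, likelihood and MCMC optimisation."""

import dataclasses

import numpy as np
import pytest
import scipy.linalg

import ratescape as rs
from ratescape.discretize import TransitionCounts
from ratescape.infer import _spectral_propagator


def random_model(rng, n=6, tau=0.3, grid_range=(0.0, 3.0)):
    grid = rs.Grid(n=n, v_lo=grid_range[0], v_hi=grid_range[1])
    return rs.RateModel(
        log_rates=rng.normal(0.0, 0.7, n + 1),
        log_p=rng.normal(0.0, 0.7, n),
        grid=grid,
        tau=tau,
    )


def five_bin_truth():
    """A known 5-bin model and its exact expected counts (1e5 windows/column)."""
    n = 5
    grid = rs.Grid(n=n, v_lo=0.0, v_hi=1.0)
    dv = grid.dv
    G = 1.5 * np.sin(np.linspace(0, 3, n))
    p = np.exp(-G)
    p /= p.sum()
    D_centers = 0.02 + 0.01 * np.arange(n)
    D_edges = 0.5 * (D_centers[:-1] + D_centers[1:])
    tau = dv * dv / (2 * D_centers.mean())
    up = (D_edges / dv**2) * np.sqrt(p[1:] / p[:-1])
    log_rates = np.log(np.concatenate([[D_centers[0] / dv**2], up, [D_centers[-1] / dv**2]]))
    truth = rs.RateModel(log_rates=log_rates, log_p=np.log(p), grid=grid, tau=tau)
    P = rs.propagator(rs.build_rate_matrix(truth), tau)
    N = np.rint(P * 100_000).astype(np.int64)
    N[:, 0] = 0
    N[:, n + 1] = 0
    counts = TransitionCounts(counts=N, tau=tau, grid=grid)
    return truth, counts


class TestRateMatrix:
    def test_detailed_balance_by_construction(self):
        rng = np.random.default_rng(0)
        m = random_model(rng)
        R = rs.build_rate_matrix(m)
        p = m.occupancies
        for j in range(1, m.grid.n):
            # R_{j,j+1} p_{j+1} = R_{j+1,j} p_j (0-based occupancy p[j-1] is bin j)
            assert R[j, j + 1] * p[j] == pytest.approx(R[j + 1, j] * p[j - 1], rel=1e-12)

    def test_interior_columns_sum_to_zero(self):
        rng = np.random.default_rng(1)
        R = rs.build_rate_matrix(random_model(rng))
        np.testing.assert_allclose(R[:, 1:-1].sum(axis=0), 0.0, atol=1e-12)

    def test_absorbing_columns_zero(self):
        R = rs.build_rate_matrix(random_model(np.random.default_rng(2)))
        assert np.all(R[:, 0] == 0) and np.all(R[:, -1] == 0)

    def test_edge_diffusivity_round_trip(self):
        # building from (p, D) and reading D back is an exact algebraic identity
        grid = rs.Grid(n=6, v_lo=0.0, v_hi=3.0)
        rng = np.random.default_rng(3)
        G = rng.normal(0, 1, 6)
        D_edges = np.exp(rng.normal(-3, 0.5, 5))
        m = rs.model_from_profiles(grid, 0.2, G=G, D_edges=D_edges)
        prof = rs.extract_profiles(m)
        np.testing.assert_allclose(prof.D_edges, D_edges, rtol=1e-12)
        G_shifted = G - G[np.argmin(np.abs(grid.centers - 1.5))]
        np.testing.assert_allclose(prof.G_centers, G_shifted, atol=1e-12)


class TestPropagator:
    def test_zero_lag_is_identity(self):
        R = rs.build_rate_matrix(random_model(np.random.default_rng(4)))
        np.testing.assert_allclose(rs.propagator(R, 0.0), np.eye(R.shape[0]), atol=1e-14)

    def test_two_state_closed_form(self):
        k1, k2, tau = 0.7, 1.9, 0.63
        R = np.array([[-k1, k2], [k1, -k2]])
        lam = k1 + k2
        e = np.exp(-lam * tau)
        expected = np.array([[k2 + k1 * e, k2 * (1 - e)], [k1 * (1 - e), k1 + k2 * e]]) / lam
        np.testing.assert_allclose(rs.propagator(R, tau), expected, atol=1e-12)

    def test_interior_block_identity(self):
        # block-triangular structure: interior block of exp(tau R) equals the
        # exponential of the interior sub-generator (diagonal keeps losses)
        m = random_model(np.random.default_rng(5))
        R = rs.build_rate_matrix(m)
        P = rs.propagator(R, m.tau)
        P_sub = scipy.linalg.expm(m.tau * R[1:-1, 1:-1])
        np.testing.assert_allclose(P[1:-1, 1:-1], P_sub, atol=1e-10)

    def test_spectral_route_matches_expm(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            m = random_model(rng, n=int(rng.integers(3, 12)))
            P = rs.propagator(rs.build_rate_matrix(m), m.tau)
            P_int, p_left, p_right = _spectral_propagator(m)
            np.testing.assert_allclose(P[1:-1, 1:-1], P_int, atol=1e-12)
            np.testing.assert_allclose(P[0, 1:-1], p_left, atol=1e-12)
            np.testing.assert_allclose(P[-1, 1:-1], p_right, atol=1e-12)

    def test_stochasticity_over_random_models(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            m = random_model(rng, n=int(rng.integers(3, 10)))
            P = rs.propagator(rs.build_rate_matrix(m), m.tau)
            assert np.max(np.abs(P.sum(axis=0) - 1.0)) < 1e-10
            assert P.min() >= 0.0 and P.max() <= 1.0 + 1e-12

    def test_stationarity_without_absorption(self):
        # reflective variant: detailed balance makes p stationary
        rng = np.random.default_rng(8)
        for _ in range(20):
            m = random_model(rng, n=int(rng.integers(3, 10)))
            n = m.grid.n
            R = np.zeros((n, n))
            j = np.arange(n - 1)
            R[j + 1, j] = m.up_rates
            R[j, j + 1] = m.down_rates
            R[np.arange(n), np.arange(n)] = -R.sum(axis=0)
            P = rs.propagator(R, m.tau)
            p = m.occupancies
            np.testing.assert_allclose(P @ p, p, atol=1e-10)


class TestLikelihood:
    def test_zero_counts(self):
        m = random_model(np.random.default_rng(9))
        counts = TransitionCounts(
            counts=np.zeros((m.grid.n + 2,) * 2, dtype=np.int64), tau=m.tau, grid=m.grid
        )
        assert rs.log_likelihood(m, counts) == 0.0

    def test_single_count(self):
        m = random_model(np.random.default_rng(10))
        P = rs.propagator(rs.build_rate_matrix(m), m.tau)
        N = np.zeros_like(P, dtype=np.int64)
        N[3, 2] = 1
        counts = TransitionCounts(counts=N, tau=m.tau, grid=m.grid)
        assert rs.log_likelihood(m, counts) == pytest.approx(np.log(P[3, 2]), rel=1e-12)

    def test_brute_force_window_product(self):
        # n = 3: ln L equals the log of the product of per-window propagator entries
        rng = np.random.default_rng(11)
        m = random_model(rng, n=3)
        P = rs.propagator(rs.build_rate_matrix(m), m.tau)
        N = rng.integers(0, 7, size=(5, 5))
        N[:, 0] = 0
        N[:, -1] = 0
        counts = TransitionCounts(counts=N, tau=m.tau, grid=m.grid)
        brute = 0.0
        for i in range(5):
            for j in range(5):
                for _ in range(N[i, j]):
                    brute += np.log(P[i, j])
        assert rs.log_likelihood(m, counts) == pytest.approx(brute, rel=1e-12, abs=1e-12)

    def test_gauge_invariance(self):
        m = random_model(np.random.default_rng(12))
        truth, counts = five_bin_truth()
        lnL = rs.log_likelihood(truth, counts)
        shifted = dataclasses.replace(truth, log_p=truth.log_p + 3.7)
        assert rs.log_likelihood(shifted, counts) == pytest.approx(lnL, rel=1e-12)

    def test_grid_mismatch_rejected(self):
        truth, counts = five_bin_truth()
        other = dataclasses.replace(truth, tau=truth.tau * 2)
        with pytest.raises(Exception):
            rs.log_likelihood(other, counts)


class TestExtraction:
    def test_uniform_occupancy_gives_flat_G(self):
        grid = rs.Grid(n=5, v_lo=0.0, v_hi=1.0)
        m = rs.model_from_profiles(grid, 0.1)
        np.testing.assert_allclose(rs.extract_profiles(m).G_centers, 0.0, atol=1e-14)

    def test_doubling_rates_doubles_D_leaves_G(self):
        m = random_model(np.random.default_rng(13))
        prof = rs.extract_profiles(m)
        doubled = dataclasses.replace(m, log_rates=m.log_rates + np.log(2.0))
        prof2 = rs.extract_profiles(doubled)
        np.testing.assert_allclose(prof2.D_edges, 2 * prof.D_edges, rtol=1e-12)
        np.testing.assert_allclose(prof2.G_centers, prof.G_centers, atol=1e-12)


class TestOptimisation:
    def test_large_count_self_consistency(self):
        # expected counts from a known model: the likelihood maximiser must
        # approach the generating model (and dominate its likelihood)
        truth, counts = five_bin_truth()
        lnL_true = rs.log_likelihood(truth, counts)
        cfg = rs.McmcConfig(steps=20_000, seed=3, polish=True)
        model, diag = rs.mcmc_optimize(counts, truth.grid, cfg)
        assert diag["log_likelihood"] >= lnL_true - 1e-6
        ref = rs.extract_profiles(truth)
        got = rs.extract_profiles(model)
        assert np.abs(got.G_centers - ref.G_centers).max() < 0.05
        assert np.abs(got.D_edges / ref.D_edges - 1).max() < 0.02

    def test_chain_determinism(self):
        truth, counts = five_bin_truth()
        cfg = rs.McmcConfig(steps=2_000, seed=5)
        m1, d1 = rs.mcmc_optimize(counts, truth.grid, cfg)
        m2, d2 = rs.mcmc_optimize(counts, truth.grid, cfg)
        np.testing.assert_array_equal(m1.log_rates, m2.log_rates)
        np.testing.assert_array_equal(m1.log_p, m2.log_p)
        assert d1["log_likelihood"] == d2["log_likelihood"]

    def test_prescribed_free_energy_mode(self):
        truth, counts = five_bin_truth()
        cfg = rs.McmcConfig(steps=8_000, seed=2, polish=True,
                            fixed_free_energy=-truth.log_p)
        model, _ = rs.mcmc_optimize(counts, truth.grid, cfg)
        # occupancies frozen to the prescribed profile
        np.testing.assert_allclose(
            model.log_p - model.log_p[0], truth.log_p - truth.log_p[0], atol=1e-12
        )
        ref = rs.extract_profiles(truth)
        got = rs.extract_profiles(model)
        assert np.abs(got.D_edges / ref.D_edges - 1).max() < 0.02


class TestReplicates:
    def test_single_replicate_zero_std(self):
        truth, counts = five_bin_truth()
        prof = rs.replicate_inference(
            counts, truth.grid, rs.McmcConfig(steps=2_000, replicates=1, seed=1)
        )
        assert np.all(prof.G_std == 0) and np.all(prof.D_std == 0)

    def test_low_noise_limit_small_spread(self):
        truth, counts = five_bin_truth()
        prof = rs.replicate_inference(
            counts, truth.grid,
            rs.McmcConfig(steps=5_000, replicates=5, seed=4, polish=True),
        )
        assert np.all(prof.D_std < 0.05 * prof.D_edges)

    def test_replicate_determinism(self):
        truth, counts = five_bin_truth()
        cfg = rs.McmcConfig(steps=2_000, replicates=3, seed=6)
        p1 = rs.replicate_inference(counts, truth.grid, cfg)
        p2 = rs.replicate_inference(counts, truth.grid, cfg)
        np.testing.assert_array_equal(p1.G_centers, p2.G_centers)
        np.testing.assert_array_equal(p1.D_std, p2.D_std)
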