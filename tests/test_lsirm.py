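"""Latent-space item-response model: likelihood, sampler, alignment."""

import numpy as np
import pytest

from fcnfusion.lsirm import (
    LsirmParams,
    McmcConfig,
    log_likelihood,
    origin_proximity,
    procrustes_align,
    rotate_positions,
    run_mcmc,
)
from fcnfusion.rotation import oblimin_criterion, oblimin_rotate


def rotation(theta, reflect=False):
    Q = np.array([[np.cos(theta), -np.sin(theta)],
                  [np.sin(theta), np.cos(theta)]])
    return Q @ np.diag([1, -1]) if reflect else Q


class TestLogLikelihood:
    def test_exact_fit_single_cell(self):
        s2 = 0.7
        params = LsirmParams(theta=np.array([1.3]), beta=np.array([-0.4]),
                             U=np.zeros((1, 2)), V=np.zeros((1, 2)), sigma2=s2)
        y = np.array([[1.3 - 0.4]])
        assert log_likelihood(y, params) == pytest.approx(
            -0.5 * np.log(2 * np.pi * s2)
        )

    def test_matches_four_term_loop(self):
        rng = np.random.default_rng(0)
        params = LsirmParams(
            theta=rng.standard_normal(2), beta=rng.standard_normal(2),
            U=rng.standard_normal((2, 2)), V=rng.standard_normal((2, 2)),
            sigma2=0.5,
        )
        y = rng.standard_normal((2, 2))
        expected = 0.0
        for i in range(2):
            for j in range(2):
                mu = (params.theta[j] + params.beta[i]
                      - np.linalg.norm(params.U[j] - params.V[i]))
                expected += (-0.5 * np.log(2 * np.pi * 0.5)
                             - (y[i, j] - mu) ** 2 / (2 * 0.5))
        assert log_likelihood(y, params) == pytest.approx(expected, abs=1e-12)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(1)
        theta, beta = rng.standard_normal(6), rng.standard_normal(9)
        U, V = rng.standard_normal((6, 2)), rng.standard_normal((9, 2))
        y = rng.standard_normal((9, 6))
        base = log_likelihood(y, LsirmParams(theta, beta, U, V, 0.3))
        Q, t = rotation(1.1, reflect=True), np.array([5.0, -2.0])
        moved = log_likelihood(
            y, LsirmParams(theta, beta, U @ Q.T + t, V @ Q.T + t, 0.3)
        )
        assert moved == pytest.approx(base, abs=1e-10)

    def test_invalid_variance_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            LsirmParams(np.zeros(1), np.zeros(1), np.zeros((1, 2)),
                        np.zeros((1, 2)), sigma2=0.0)


class TestSampler:
    def test_retained_draw_count_identity(self):
        assert McmcConfig().n_retained == 10_000  # 55k / 5k burn-in / thin 5
        cfg = McmcConfig(n_iterations=600, burn_in=100, thin=5, seed=0)
        post = run_mcmc(np.random.default_rng(2).normal(size=(6, 4)), cfg)
        assert post.n_retained == cfg.n_retained == 100
        assert post.theta.shape == (100, 4)

    def test_same_seed_identical_chains(self):
        y = np.random.default_rng(3).normal(size=(8, 5))
        cfg = McmcConfig(n_iterations=400, burn_in=100, thin=3, seed=9)
        a, b = run_mcmc(y, cfg), run_mcmc(y, cfg)
        np.testing.assert_array_equal(a.theta, b.theta)
        np.testing.assert_array_equal(a.U, b.U)
        np.testing.assert_array_equal(a.sigma2, b.sigma2)

    def test_conjugate_reduction_matches_closed_form(self, recovery_data):
        # freeze everything but theta at truth with known variances: the
        # theta posterior is Normal with closed-form mean
        y, truth = recovery_data
        s2 = truth["noise_sd"] ** 2
        st2 = 1.0
        cfg = McmcConfig(n_iterations=30_000, burn_in=5_000, thin=5,
                         jump_theta=0.05, seed=11)
        post = run_mcmc(
            y, cfg,
            init={"U": truth["U"], "V": truth["V"], "beta": truth["beta"],
                  "sigma2": s2, "sigma_theta2": st2},
            frozen={"U", "V", "beta", "sigma2", "sigma_theta2"},
        )
        resid = y + truth["distances"] - truth["beta"][:, None]
        precision = y.shape[0] / s2 + 1.0 / st2
        closed_mean = resid.sum(axis=0) / s2 / precision
        mc_se = post.theta.std(axis=0) / np.sqrt(200)  # conservative ESS
        assert np.all(np.abs(post.theta.mean(axis=0) - closed_mean) < 3 * mc_se)

    def test_acceptance_rates_in_open_interval(self, recovery_posterior):
        for block, rate in recovery_posterior.acceptance_rates.items():
            assert 0.05 < rate < 0.95, f"{block}: {rate}"

    def test_distance_recovery(self, recovery_data, recovery_posterior):
        _, truth = recovery_data
        mp = recovery_posterior.mean_params()
        est = np.linalg.norm(mp.U[None, :, :] - mp.V[:, None, :], axis=2)
        r = np.corrcoef(est.ravel(), truth["distances"].ravel())[0, 1]
        assert r >= 0.8

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            McmcConfig(burn_in=100, n_iterations=100)
        with pytest.raises(ValueError):
            McmcConfig(thin=0)
        with pytest.raises(ValueError):
            McmcConfig(jump_u=0.0)


class TestAlignment:
    def test_exact_rotations_recovered(self):
        rng = np.random.default_rng(4)
        U0, V0 = rng.standard_normal((10, 2)), rng.standard_normal((15, 2))
        Us, Vs = [U0], [V0]
        for k in range(100):
            Q = rotation(rng.uniform(0, 2 * np.pi), reflect=bool(k % 2))
            Us.append(U0 @ Q)
            Vs.append(V0 @ Q)
        aU, aV = procrustes_align(np.array(Us), np.array(Vs))
        assert np.abs(aU - U0).max() < 1e-8
        assert np.abs(aV - V0).max() < 1e-8

    def test_alignment_preserves_relative_distances(self, recovery_posterior):
        post = recovery_posterior
        t = 7
        d_raw = np.linalg.norm(
            post.U[t][None] - post.V[t][:, None], axis=2
        )
        d_aligned = np.linalg.norm(
            post.aligned_U[t][None] - post.aligned_V[t][:, None], axis=2
        )
        np.testing.assert_allclose(d_aligned, d_raw, atol=1e-9)

    def test_degenerate_configuration_warns(self):
        U = np.zeros((2, 3, 2))
        V = np.zeros((2, 4, 2))
        with pytest.warns(UserWarning, match="degenerate"):
            procrustes_align(U, V)


class TestRotation:
    def test_criterion_never_increases(self):
        rng = np.random.default_rng(5)
        A = rng.standard_normal((30, 2))
        out = rotate_positions(A)
        assert out["criterion_after"] <= out["criterion_before"] + 1e-12
        assert out["rotated"].shape == (30, 2)

    def test_perfect_simple_structure_left_unchanged(self):
        # each row loads on exactly one axis: quartimin criterion is 0, the
        # global minimum, so the rotation is the identity
        rng = np.random.default_rng(6)
        A = np.zeros((20, 2))
        A[:10, 0] = rng.uniform(0.5, 2.0, 10)
        A[10:, 1] = rng.uniform(0.5, 2.0, 10)
        L, T, f = oblimin_rotate(A)
        assert f == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(T, np.eye(2), atol=1e-10)
        np.testing.assert_allclose(L, A, atol=1e-10)

    def test_converged_solution_is_stationary(self):
        rng = np.random.default_rng(9)
        L, T, f = oblimin_rotate(rng.standard_normal((20, 2)))
        _, Gq = oblimin_criterion(L)
        Ti = np.linalg.inv(T)
        G = -(L.T @ Gq @ Ti).T
        Gp = G - T @ np.diag(np.sum(T * G, axis=0))
        assert np.linalg.norm(Gp) < 1e-6

    def test_full_atlas_shape_preserved(self):
        rng = np.random.default_rng(7)
        out = rotate_positions(rng.standard_normal((116, 2)))
        assert out["rotated"].shape == (116, 2)

    def test_criterion_gradient_consistent(self):
        rng = np.random.default_rng(8)
        L = rng.standard_normal((6, 2))
        f, G = oblimin_criterion(L)
        eps = 1e-6
        for idx in [(0, 0), (3, 1)]:
            Lp = L.copy(); Lp[idx] += eps
            Lm = L.copy(); Lm[idx] -= eps
            num = (oblimin_criterion(Lp)[0] - oblimin_criterion(Lm)[0]) / (2 * eps)
            assert G[idx] == pytest.approx(num, rel=1e-4)


class TestOriginProximity:
    def test_origin_roi_ranked_first_and_quartile_flag(self, recovery_posterior):
        prox = origin_proximity(recovery_posterior)
        assert (np.diff(prox["distance"].to_numpy()) >= 0).all()
        assert int(prox["near_origin"].sum()) == 30 // 4

    def test_zero_position_rank_one(self):
        from fcnfusion.lsirm import LsirmPosterior

        U = np.array([[[1.0, 1.0], [0.0, 0.0], [2.0, 0.0], [0.5, 0.5]]])
        post = LsirmPosterior(
            theta=np.zeros((1, 4)), beta=np.zeros((1, 2)),
            U=U, V=np.zeros((1, 2, 2)),
            sigma2=np.ones(1), sigma_theta2=np.ones(1),
            acceptance_rates={}, roi_labels=["a", "b", "c", "d"],
            subject_ids=["s1", "s2"],
        )
        prox = origin_proximity(post)
        assert prox.iloc[0]["roi"] == "b"
        assert prox.iloc[0]["rank"] == 1

    def test_radius_threshold_mode(self, recovery_posterior):
        prox = origin_proximity(recovery_posterior, radius=1.0)
        flagged = prox[prox.near_origin]
        assert (flagged["distance"] <= 1.0).all()
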