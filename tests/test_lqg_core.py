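"""Plant construction, delay augmentation, gain computation, simulation."""

import numpy as np
import pytest

from dynreach import (
    ConfigurationError,
    GainSchedule,
    PlantConfig,
    ReachingModel,
    SimulationError,
    augment_delays,
    build_core_system,
    compute_gains,
    kalman_step,
    simulate_batch,
)
from dynreach.config import IDX_FE, IDX_FMC, IDX_H, IDX_P, IDX_PSTAR, IDX_V, N_CORE
from dynreach.lqg import H_P, H_V, _initial_state


class TestCoreSystem:
    def test_matrix_entries_at_defaults(self):
        cfg = PlantConfig()
        A, B = build_core_system(cfg)
        assert A[IDX_V, IDX_V] == pytest.approx(1 - 0.15 * 0.01 / 1.0)  # 0.9985
        assert A[IDX_FMC, IDX_FMC] == pytest.approx(1 - 0.010 / 0.066)
        assert B[IDX_FMC, 0] == pytest.approx(0.010 / 0.066)
        # cursor and hand rows both integrate the velocity
        assert A[IDX_P, IDX_V] == A[IDX_H, IDX_V] == cfg.dt
        # velocity couples dt/m to both muscle and external force
        assert A[IDX_V, IDX_FMC] == A[IDX_V, IDX_FE] == cfg.dt / cfg.m
        # external force and target are constants
        for idx in (IDX_FE, IDX_PSTAR):
            row = np.zeros(N_CORE)
            row[idx] = 1.0
            np.testing.assert_array_equal(A[idx], row)
        assert np.count_nonzero(B) == 1

    def test_zero_damping_free_mass_accelerates_linearly(self):
        cfg = PlantConfig(G=0.0)
        A, B = build_core_system(cfg)
        x = np.zeros(N_CORE)
        x[IDX_FMC] = 1.0  # constant muscle force, no control
        A = A.copy()
        A[IDX_FMC, IDX_FMC] = 1.0  # hold the force constant
        vs = []
        for _ in range(10):
            x = A @ x
            vs.append(x[IDX_V])
        incr = np.diff(vs)
        np.testing.assert_allclose(incr, cfg.dt / cfg.m, rtol=1e-12)

    @pytest.mark.parametrize("bad", [
        {"dt": 0.0}, {"m": -1.0}, {"tau_muscle": 0.0}, {"delta_p": 10},
        {"N": 5}, {"sigma_additive": -0.1},
    ])
    def test_invalid_configuration_rejected(self, bad):
        with pytest.raises(ConfigurationError):
            PlantConfig(**bad)


class TestAugmentation:
    def test_dimension_and_observation_blocks(self):
        cfg = PlantConfig()
        sys = augment_delays(build_core_system(cfg), cfg)
        assert sys.n_aug == 6 * (cfg.delta_v + 1) == 60
        assert sys.H.shape == (12, 60)
        np.testing.assert_array_equal(
            sys.H[:6, cfg.delta_p * 6:(cfg.delta_p + 1) * 6], H_P)
        np.testing.assert_array_equal(
            sys.H[6:, cfg.delta_v * 6:(cfg.delta_v + 1) * 6], H_V)
        # exactly two nonzero block-columns
        other = sys.H.copy()
        other[:6, cfg.delta_p * 6:(cfg.delta_p + 1) * 6] = 0
        other[6:, cfg.delta_v * 6:(cfg.delta_v + 1) * 6] = 0
        assert not other.any()
        # observation noise is block-diagonal with the 2.3 variance ratio
        w = np.diag(sys.Sigma_omega)
        assert np.allclose(w[:6], cfg.Sigma_p_scale)
        assert np.allclose(w[6:], cfg.Sigma_p_scale / 2.3)

    def test_shift_register_property(self, results):
        rec = results.simulate_trial("PV_align", seed=7)
        x = rec.x_true
        for t in range(1, x.shape[0]):
            for k in range(1, results.model.config.delta_v + 1):
                np.testing.assert_array_equal(
                    x[t, k * 6:(k + 1) * 6], x[t - 1, (k - 1) * 6:k * 6])

    def test_degenerate_zero_delay_equals_core(self):
        cfg = PlantConfig(delta_p=0, delta_v=0, N=20)
        A6, B6 = build_core_system(cfg)
        sys = augment_delays((A6, B6), cfg)
        assert sys.n_aug == 6
        np.testing.assert_array_equal(sys.A, A6)
        np.testing.assert_array_equal(sys.H, np.vstack([H_P, H_V]))

    def test_delay_order_enforced(self):
        with pytest.raises(ConfigurationError):
            PlantConfig(delta_p=10, delta_v=9)


def _oracle_lqr(A, B, Q_list, R):
    """Independent textbook backward Riccati recursion."""
    N = len(Q_list)
    S = Q_list[-1].copy()
    L = [None] * N
    L[N - 1] = np.zeros((1, A.shape[0]))
    for t in range(N - 2, -1, -1):
        Lt = np.linalg.solve(R + B.T @ S @ B, B.T @ S @ A)
        S = Q_list[t] + A.T @ S @ (A - B @ Lt)
        L[t] = Lt
    return L


def _oracle_kalman(A, H, Sigma_xi, Sigma_omega, N):
    """Independent predictor-form Kalman recursion, zero initial uncertainty."""
    P = np.zeros((A.shape[0], A.shape[0]))
    Ks = []
    for _ in range(N - 1):
        S = H @ P @ H.T + Sigma_omega
        K = A @ P @ H.T @ np.linalg.inv(S)
        Ks.append(K)
        P = A @ P @ A.T + Sigma_xi - K @ S @ K.T
    return Ks


class TestGains:
    def test_matches_classical_riccati_and_kalman(self, oracle_config):
        cfg = oracle_config
        sys = augment_delays(build_core_system(cfg), cfg)
        gains = compute_gains(sys, cfg)
        assert gains.converged

        q = np.zeros(6)
        q[IDX_P], q[IDX_PSTAR] = 1.0, -1.0
        Q = np.outer(q, q)
        L_ref = _oracle_lqr(sys.A, sys.B, [Q] * cfg.N, np.atleast_2d(cfg.R))
        for t in range(cfg.N):
            np.testing.assert_allclose(gains.L[t], -L_ref[t][0], atol=1e-8)

        K_ref = _oracle_kalman(sys.A, sys.H, sys.Sigma_xi, sys.Sigma_omega, cfg.N)
        for t in range(cfg.N - 1):
            np.testing.assert_allclose(gains.K[t], K_ref[t], atol=1e-8)

    def test_infinite_control_cost_kills_control(self):
        cfg = PlantConfig(N=40, p_star=0.2, R=1e9)
        res = ReachingModel(cfg).fit()
        assert np.max(np.abs(res.L)) < 1e-3

    def test_local_optimality_of_gains(self):
        """Simulated expected cost is lowest at the computed gains.

        Probed with signal-dependent motor noise, sensory delays and
        partial observability all active.  The internal prediction noise
        is disabled here: it correlates the estimation error with the
        estimate, a correlation the coupled iteration (by construction)
        treats as zero, so the gains are exactly optimal within the
        linear-in-estimate policy class only in its absence.
        """
        cfg = PlantConfig(p_star=0.2, Sigma_internal=0.0)
        res = ReachingModel(cfg).fit()
        from dynreach.lqg import _cost_schedule

        w = _cost_schedule(res.system)

        def expected_cost(scale, seed=123, n=600):
            g = res.gains
            g2 = GainSchedule(L=scale * g.L, K=g.K, converged=True,
                              iterations=0, max_delta=0.0)
            sim = simulate_batch(res.system, g2, n_trials=n, seed=seed)
            # reconstruct the quadratic cost from the recorded series
            perr = (sim["p"] - cfg.p_star) ** 2
            J = (w[:, None] * perr).sum(axis=0) + cfg.R * (sim["u"] ** 2).sum(axis=0)
            return J.mean()

        j1 = expected_cost(1.0)
        assert j1 <= expected_cost(1.1)
        assert j1 <= expected_cost(0.9)


class TestEstimator:
    def test_zero_innovation_returns_prior(self, results):
        sys = results.system
        rng = np.random.default_rng(0)
        x_hat = rng.standard_normal(sys.n_aug)
        u = 0.7
        y = sys.H @ x_hat  # observation equals the lagged prior exactly
        out = kalman_step(x_hat, u, y, results.gains.K[3], sys)
        np.testing.assert_allclose(out, sys.A @ x_hat + (sys.B * u).ravel(),
                                   atol=1e-12)

    def test_matches_independent_filter_on_delay_free_system(self, oracle_config):
        cfg = oracle_config
        sys = augment_delays(build_core_system(cfg), cfg)
        gains = compute_gains(sys, cfg)
        rng = np.random.default_rng(42)
        x_hat = _initial_state(sys).astype(float)
        x_ref = x_hat.copy()
        for t in range(100):
            u = float(rng.standard_normal())
            y = rng.standard_normal(12)
            K = gains.K[min(t, cfg.N - 1)]
            x_hat = kalman_step(x_hat, u, y, K, sys)
            # independently coded classical predictor-form filter
            x_ref = (sys.A @ x_ref + (sys.B * u).ravel()
                     + K @ (y - sys.H @ x_ref))
            np.testing.assert_allclose(x_hat, x_ref, atol=1e-10)

    def test_no_vision_drops_visual_innovation_entirely(self, results):
        sys = results.system
        rng = np.random.default_rng(1)
        x_hat = rng.standard_normal(sys.n_aug)
        y = rng.standard_normal(12)
        K = results.gains.K[10]
        no_vis = kalman_step(x_hat, 0.2, y, K, sys, vision=False)
        # equivalent to using only the proprioceptive block-row of H
        manual = (sys.A @ x_hat + (sys.B * 0.2).ravel()
                  + K[:, :6] @ (y[:6] - sys.H_prop @ x_hat))
        np.testing.assert_allclose(no_vis, manual, atol=1e-12)


class TestSimulation:
    def test_noise_free_reach_hits_target(self):
        res = ReachingModel(PlantConfig(p_star=0.2)).fit()
        sim = res.simulate(noise=False)
        assert abs(sim["p"][-1, 0] - 0.2) < 1e-3  # within 1 mm at horizon end

    def test_fixed_seed_reproducible(self, results, specs):
        a = results.simulate(specs["PV_align"], n_trials=5, seed=99)
        b = results.simulate(specs["PV_align"], n_trials=5, seed=99)
        for key in ("p", "h", "v", "u"):
            np.testing.assert_array_equal(a[key], b[key])

    def test_mean_trajectory_matches_noise_free(self, results, specs):
        """Zero-mean noises: the across-trial mean converges on the
        deterministic trajectory within Monte-Carlo error."""
        spec = specs["PV_align"]
        noisy = results.simulate(spec, n_trials=3000, seed=5)
        clean = results.simulate(spec, noise=False)
        mean_h = noisy["h"].mean(axis=1)
        mc_se = noisy["h"].std(axis=1).max() / np.sqrt(3000)
        assert np.max(np.abs(mean_h - clean["h"][:, 0])) < 6 * mc_se

    def test_divergence_raises_with_step_index(self, results):
        bad = GainSchedule(L=-1e9 * results.gains.L, K=results.gains.K,
                           converged=True, iterations=0, max_delta=0.0)
        with pytest.raises(SimulationError) as err:
            simulate_batch(results.system, bad, n_trials=1, seed=0)
        assert err.value.step > 0

    def test_masked_vision_recorded_absent(self, results, specs):
        rec = results.simulate_trial(specs["P_nov"], seed=3)
        onset = specs["P_nov"].onset_step
        assert np.isnan(rec.y[onset:, 6:]).all()
        assert np.isfinite(rec.y[:, :6]).all()
        assert not rec.vision_mask[onset:].any()
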