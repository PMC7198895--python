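import numpy as np
import pytest

from dbiwin.inference import (
    FourierModel,
    InferenceSettings,
    ModelState,
    SingularModelError,
    evaluate_basis,
    flat_prior,
    infer_block,
    propagate_prior,
    quadrature_covariance,
    run_sequential,
)
from dbiwin.simulators import PhasePairConfig, simulate_phase_pair


class TestBasis:
    def test_constant_term_is_ones(self):
        m = FourierModel(order=2)
        phi = np.random.default_rng(0).uniform(0, 7, 50)
        Phi, dPhi = evaluate_basis(phi, phi[::-1], m)
        assert np.all(Phi[:, 0] == 1.0)
        assert np.all(dPhi[:, 0] == 0.0)

    def test_order_one_at_zero_phases(self):
        m = FourierModel(order=1)
        Phi, _ = evaluate_basis(np.zeros(3), np.zeros(3), m)
        labels = m.term_labels()
        for j, lab in enumerate(labels):
            expected = 1.0 if (lab == "const" or lab.startswith("cos")) else 0.0
            assert np.allclose(Phi[:, j], expected)

    def test_derivative_matches_finite_difference(self):
        m = FourierModel(order=2)
        rng = np.random.default_rng(1)
        own = rng.uniform(0, 2 * np.pi, 40)
        partner = rng.uniform(0, 2 * np.pi, 40)
        Phi, dPhi = evaluate_basis(own, partner, m)
        eps = 1e-7
        Phi_p, _ = evaluate_basis(own + eps, partner, m)
        fd = (Phi_p - Phi) / eps
        assert np.abs(fd - dPhi).max() < 1e-5

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            evaluate_basis(np.zeros(3), np.zeros(4), FourierModel())

    def test_term_indexing(self):
        m = FourierModel(order=2)
        assert m.term_index("const") == 0
        # sin(phi_partner): k=0, s=1
        j = m.term_index("sin", 0, 1)
        Phi, _ = evaluate_basis(np.zeros(4), np.full(4, 0.5), m)
        assert np.allclose(Phi[:, j], np.sin(0.5))
        assert m.n_params == 25
        assert len(m.coupling_indices()) == 20


class TestInferBlock:
    def test_flat_prior_zero_noise_equals_least_squares(self):
        # independent oracle: OLS of finite-difference velocities on the basis
        cfg = PhasePairConfig(duration=30.0, E11=0, E22=0, mod_omega=0,
                              mod_a3=0, seed=4)
        s = simulate_phase_pair(cfg)
        settings = InferenceSettings(t_w=30.0, p_w=0.2, order=1)
        m = settings.model
        post = infer_block((s.phi1, s.phi2), flat_prior(m), settings, s.h)
        mid1 = 0.5 * (s.phi1[1:] + s.phi1[:-1])
        mid2 = 0.5 * (s.phi2[1:] + s.phi2[:-1])
        P1, _ = evaluate_basis(mid1, mid2, m)
        P2, _ = evaluate_basis(mid2, mid1, m)
        ols = np.concatenate([
            np.linalg.lstsq(P1, np.diff(s.phi1) / s.h, rcond=None)[0],
            np.linalg.lstsq(P2, np.diff(s.phi2) / s.h, rcond=None)[0],
        ])
        assert np.abs(post.c - ols).max() < 1e-8

    def test_zero_noise_recovers_generating_parameters(self):
        cfg = PhasePairConfig(duration=40.0, E11=0, E22=0, mod_omega=0,
                              mod_a3=0, seed=4)
        s = simulate_phase_pair(cfg)
        settings = InferenceSettings(t_w=40.0, p_w=0.2, order=1)
        m = settings.model
        post = infer_block((s.phi1, s.phi2), flat_prior(m), settings, s.h)
        assert post.c[0] == pytest.approx(cfg.omega1_const, abs=1e-3)
        assert post.c[m.term_index("sin", 1, 0)] == pytest.approx(cfg.a1, abs=1e-3)
        assert post.c[m.term_index("sin", 0, 1)] == pytest.approx(
            cfg.a3_const, abs=1e-3
        )
        j2 = m.global_index(2, m.term_index("sin", 1, 0))
        assert post.c[j2] == pytest.approx(cfg.a4, abs=1e-3)

    def test_frozen_prior_pins_posterior(self):
        cfg = PhasePairConfig(duration=20.0, seed=4)
        s = simulate_phase_pair(cfg)
        settings = InferenceSettings(t_w=20.0, p_w=0.2, order=1)
        m = settings.model
        rng = np.random.default_rng(0)
        c0 = rng.normal(size=m.n_total)
        tau = 1e12
        prior = ModelState(
            c=c0, E=np.zeros((2, 2)),
            Xi=np.eye(m.n_total) * tau, Sigma=np.eye(m.n_total) / tau,
        )
        post = infer_block((s.phi1, s.phi2), prior, settings, s.h)
        assert np.abs(post.c - c0).max() < 1e-4

    def test_too_short_block_raises_singular(self):
        s = simulate_phase_pair(PhasePairConfig(duration=10.0, seed=0))
        settings = InferenceSettings(t_w=0.5, p_w=0.2, order=2)
        with pytest.raises(SingularModelError):
            infer_block((s.phi1[:51], s.phi2[:51]), flat_prior(settings.model),
                        settings, s.h)

    def test_oscillator_relabelling_permutes_parameters(self):
        cfg = PhasePairConfig(duration=60.0, seed=12)
        s = simulate_phase_pair(cfg)
        settings = InferenceSettings(t_w=60.0, p_w=0.2)
        m = settings.model
        L = m.n_params
        a = infer_block((s.phi1, s.phi2), flat_prior(m), settings, s.h)
        b = infer_block((s.phi2, s.phi1), flat_prior(m), settings, s.h)
        assert np.allclose(a.c[:L], b.c[L:], atol=1e-6)
        assert np.allclose(a.c[L:], b.c[:L], atol=1e-6)
        assert a.E[0, 0] == pytest.approx(b.E[1, 1], rel=1e-6)


class TestPropagation:
    def _state(self, c, sigma_diag):
        n = len(c)
        return ModelState(
            c=np.asarray(c, float), E=np.zeros((2, 2)),
            Xi=np.diag(1.0 / np.asarray(sigma_diag, float)),
            Sigma=np.diag(np.asarray(sigma_diag, float)),
        )

    def test_hand_computed_diffusion(self):
        m = FourierModel(order=1)
        c = np.zeros(m.n_total)
        c[0], c[1] = 1.0, 2.0
        post = self._state(c, np.full(m.n_total, 0.01))
        prior = propagate_prior(post, InferenceSettings(t_w=1, p_w=0.2, order=1))
        d = np.diag(prior.Sigma)
        assert d[0] == pytest.approx(0.01 + 0.04)
        assert d[1] == pytest.approx(0.01 + 0.16)
        assert np.allclose(d[2:], 0.01)
        assert np.allclose(prior.c, post.c)
        assert np.allclose(prior.Xi @ prior.Sigma, np.eye(m.n_total), atol=1e-9)

    def test_zero_propagation_preserves_covariance(self):
        m = FourierModel(order=1)
        post = self._state(np.ones(m.n_total), np.full(m.n_total, 0.5))
        prior = propagate_prior(post, InferenceSettings(t_w=1, p_w=0.0, order=1))
        assert np.allclose(prior.Sigma, post.Sigma)

    def test_zero_parameter_entry_not_diffused(self):
        m = FourierModel(order=1)
        c = np.ones(m.n_total)
        c[3] = 0.0
        post = self._state(c, np.full(m.n_total, 0.02))
        prior = propagate_prior(post, InferenceSettings(t_w=1, p_w=0.3, order=1))
        assert prior.Sigma[3, 3] == pytest.approx(0.02)


class TestQuadratureCovariance:
    def test_closed_forms(self):
        assert quadrature_covariance(np.zeros((4, 4))) == 0.0
        assert quadrature_covariance(np.eye(6)) == 6.0
        assert quadrature_covariance(np.diag([0.1, 0.2])) == pytest.approx(0.05)

    def test_rejects_non_square(self):
        with pytest.raises(ValueError):
            quadrature_covariance(np.zeros((2, 3)))


class TestRunSequential:
    def test_stationary_parameters_are_flat(self, stationary_series):
        run = run_sequential(
            stationary_series, InferenceSettings(t_w=40.0, p_w=0.2)
        )
        C = run.parameter_series()[2:]
        # natural frequency of oscillator 2 is constant in the generator
        j = run.settings.model.global_index(2, 0)
        assert C[:, j].std() < 0.05
        assert C[:, j].mean() == pytest.approx(2 * np.pi * 1.1, rel=0.01)

    def test_noise_recovery_within_ten_percent(self, stationary_series):
        run = run_sequential(
            stationary_series, InferenceSettings(t_w=50.0, p_w=0.2)
        )
        sqrtE = run.noise_series()[2:].mean(axis=0)
        assert sqrtE[0] == pytest.approx(0.3, rel=0.10)
        assert sqrtE[1] == pytest.approx(0.3, rel=0.10)

    def test_covariance_shrinks_with_block_length(self, stationary_series):
        def mean_diag(t_w):
            run = run_sequential(
                stationary_series, InferenceSettings(t_w=t_w, p_w=0.2)
            )
            return np.mean([np.trace(st.Sigma) for st in run.states[2:]])

        assert mean_diag(40.0) < mean_diag(10.0)

    def test_q_sigma_recorded_per_block(self, phase_series_short):
        run = run_sequential(phase_series_short,
                             InferenceSettings(t_w=20.0, p_w=0.2))
        assert len(run.q_sigma) == len(run.states) == 10
        assert np.all(run.q_sigma >= 0)

    def test_block_errors_carry_block_index(self):
        s = simulate_phase_pair(PhasePairConfig(duration=10.0, seed=0))
        with pytest.raises(ValueError):
            run_sequential(s, InferenceSettings(t_w=8.0, p_w=0.2))

    def test_tracks_time_varying_frequency(self, phase_series_long):
        run = run_sequential(phase_series_long,
                             InferenceSettings(t_w=25.0, p_w=0.2))
        C = run.parameter_series()[2:]
        t = run.block_times[2:]
        truth = phase_series_long.ground_truth["omega1"]
        # inferred omega1(t) correlates strongly with the generating law
        nb = int(round(25.0 / phase_series_long.h))
        tb = truth[: len(run.states) * nb].reshape(-1, nb).mean(axis=1)[2:]
        r = np.corrcoef(C[:, 0], tb)[0, 1]
        assert r > 0.95
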