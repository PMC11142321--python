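"""Observability matrices, Gramians, graded metrics, and binary tests."""

import numpy as np
import pytest

from dss import (Gramian, GeneratorSpec, LinearModel, SensorSchedule,
                 UnstableSystemError, gramian_finite_horizon, gramian_ltv,
                 gramian_lyapunov, kalman_pbh_tests, ltv_observability_matrix,
                 metric_energy, metric_rank, metric_visibility,
                 observability_matrix, random_stable_lti, simulate)
from dss.metrics import ObsMatrix


class TestObservabilityMatrix:
    def test_identity_dynamics_repeat_readout(self):
        O = observability_matrix(np.eye(2), np.array([[1.0, 0.0]]), blocks=2)
        assert O.O == pytest.approx(np.array([[1.0, 0.0], [1.0, 0.0]]))
        assert metric_rank(O) == 1

    def test_shift_chain_reverses_basis(self, shift_system):
        A, C = shift_system
        O = observability_matrix(A, C, blocks=3)
        expected = np.array([[0, 0, 1], [0, 1, 0], [1, 0, 0]], dtype=float)
        assert O.O == pytest.approx(expected)
        assert metric_rank(O) == 3

    def test_zero_readout(self):
        O = observability_matrix(np.eye(3), np.zeros((1, 3)))
        assert metric_rank(O) == 0

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            observability_matrix(np.eye(3), np.ones((1, 2)))


class TestLtvObservabilityMatrix:
    def test_constant_model_reduces_to_lti(self, stable_lti):
        C = np.array([[1.0, 0.0, 0.0, 0.0]])
        sched = SensorSchedule.constant(C, 5)
        O_ltv = ltv_observability_matrix(stable_lti, sched, 0, 4)
        O_lti = observability_matrix(stable_lti.matrices, C, blocks=5)
        assert O_ltv.O == pytest.approx(O_lti.O)

    def test_identity_dynamics_stack_schedules(self, rng):
        model = LinearModel("ltv", np.stack([np.eye(3)] * 3))
        Cs = [rng.standard_normal((2, 3)) for _ in range(4)]
        sched = SensorSchedule(matrices=Cs)
        O = ltv_observability_matrix(model, sched, 0, 3)
        assert O.O == pytest.approx(np.vstack(Cs))

    def test_blocks_match_unit_vector_simulation(self, rng):
        mats = rng.standard_normal((3, 3, 3))
        model = LinearModel("ltv", mats)
        Cs = [rng.standard_normal((1, 3)) for _ in range(4)]
        sched = SensorSchedule(matrices=Cs)
        O = ltv_observability_matrix(model, sched, 0, 3)
        for i in range(3):
            e = np.zeros(3)
            e[i] = 1.0
            traj = simulate(model, e, 3)
            outputs = [Cs[k] @ traj.values[:, k] for k in range(4)]
            assert O.O[:, i] == pytest.approx(np.concatenate(outputs))

    def test_short_schedule_rejected(self, stable_lti):
        sched = SensorSchedule.constant(np.eye(4), 2)
        with pytest.raises(ValueError, match="schedule"):
            ltv_observability_matrix(stable_lti, sched, 0, 4)


class TestMetricRank:
    def test_threshold_semantics(self):
        O = ObsMatrix(np.eye(3), singular_values=np.array([1.0, 1e-9, 0.0]))
        assert metric_rank(O, rel_tol=1e-6) == 1

    def test_full_rank_identity(self):
        assert metric_rank(ObsMatrix(np.eye(4))) == 4

    def test_invalid_tolerance(self):
        with pytest.raises(ValueError):
            metric_rank(ObsMatrix(np.eye(2)), rel_tol=2.0)


class TestGramianLyapunov:
    def test_nilpotent_reduces_to_ctc(self, rng):
        C = rng.standard_normal((2, 3))
        G = gramian_lyapunov(np.zeros((3, 3)), C, "discrete")
        assert G.Go == pytest.approx(C.T @ C)

    def test_scalar_geometric_series(self):
        G = gramian_lyapunov(np.array([[0.5]]), np.array([[1.0]]), "discrete")
        assert G.Go[0, 0] == pytest.approx(4.0 / 3.0)

    def test_matches_truncated_series(self, rng):
        model = random_stable_lti(GeneratorSpec(n=4, spectral_radius=0.8,
                                                seed=11))
        A = model.matrices
        C = rng.standard_normal((1, 4))
        G = gramian_lyapunov(A, C, "discrete")
        S = np.zeros((4, 4))
        M = C.copy()
        for _ in range(400):
            S += M.T @ M
            M = M @ A
        assert np.max(np.abs(G.Go - S)) < 1e-8

    def test_unstable_discrete_rejected(self):
        with pytest.raises(UnstableSystemError, match="modulus"):
            gramian_lyapunov(1.5 * np.eye(2), np.ones((1, 2)), "discrete")

    def test_unstable_continuous_rejected(self):
        with pytest.raises(UnstableSystemError, match="real part"):
            gramian_lyapunov(np.eye(2), np.ones((1, 2)), "continuous")

    def test_continuous_solution_solves_equation(self, rng):
        A = rng.standard_normal((3, 3)) - 3 * np.eye(3)
        C = rng.standard_normal((2, 3))
        G = gramian_lyapunov(A, C, "continuous")
        assert A.T @ G.Go + G.Go @ A == pytest.approx(-C.T @ C, abs=1e-10)


class TestGramianLtv:
    def test_single_step(self, stable_lti, rng):
        C = rng.standard_normal((2, 4))
        sched = SensorSchedule.constant(C, 1)
        G = gramian_ltv(stable_lti, sched, 0, 0)
        assert G.Go == pytest.approx(C.T @ C)

    def test_constant_reduces_to_finite_horizon(self, stable_lti, rng):
        C = rng.standard_normal((1, 4))
        sched = SensorSchedule.constant(C, 6)
        G = gramian_ltv(stable_lti, sched, 0, 5)
        G2 = gramian_finite_horizon(stable_lti.matrices, C, 5)
        assert G.Go == pytest.approx(G2.Go)

    def test_equals_oto(self, rng):
        mats = rng.standard_normal((4, 3, 3))
        model = LinearModel("ltv", mats)
        sched = SensorSchedule(matrices=[rng.standard_normal((1, 3))
                                         for _ in range(5)])
        O = ltv_observability_matrix(model, sched, 0, 4)
        G = gramian_ltv(model, sched, 0, 4)
        assert np.max(np.abs(G.Go - O.O.T @ O.O)) < 1e-12

    def test_gramian_type_rejects_asymmetry(self):
        with pytest.raises(ValueError, match="symmetric"):
            Gramian(np.array([[1.0, 2.0], [0.0, 1.0]]), "ltv")


class TestEnergyAndVisibility:
    def test_zero_state_zero_energy(self):
        G = Gramian(np.eye(3), "finite-horizon")
        assert metric_energy(G, np.zeros(3)) == 0.0

    def test_scalar_energy_matches_output_series(self):
        G = gramian_lyapunov(np.array([[0.5]]), np.array([[1.0]]), "discrete")
        sim = sum(0.25**t for t in range(200))
        assert metric_energy(G, np.array([1.0])) == pytest.approx(sim)

    def test_energy_equals_simulated_output_energy(self, rng):
        model = random_stable_lti(GeneratorSpec(n=5, spectral_radius=0.85,
                                                seed=5))
        C = rng.standard_normal((2, 5))
        x0 = rng.standard_normal(5)
        G = gramian_lyapunov(model.matrices, C, "discrete")
        traj = simulate(model, x0, 400)
        energy = float(np.sum((C @ traj.values[:, :-1])**2))
        assert metric_energy(G, x0) == pytest.approx(energy, rel=1e-6)

    def test_visibility_trace(self):
        G = Gramian(np.diag([3.0, 2.0, 1.0]), "finite-horizon")
        assert metric_visibility(G) == pytest.approx(6.0)

    def test_visibility_equals_eigenvalue_sum(self, rng):
        M = rng.standard_normal((4, 4))
        G = Gramian(M @ M.T, "empirical")
        assert metric_visibility(G) == pytest.approx(
            np.sum(np.linalg.eigvalsh(G.Go)))


class TestKalmanPbh:
    def test_shift_chain_observable(self, shift_system):
        A, C = shift_system
        report = kalman_pbh_tests(A, C)
        assert report.kalman_observable and report.pbh_observable

    def test_zero_readout_unobservable(self):
        report = kalman_pbh_tests(np.eye(2), np.zeros((1, 2)))
        assert not report.kalman_observable
        assert all(not ok for *_, ok in report.pbh_per_eigenvalue)

    def test_repeated_eigenvalue_deficient_readout(self):
        report = kalman_pbh_tests(np.eye(2), np.array([[1.0, 0.0]]))
        assert not report.kalman_observable
        assert not report.pbh_observable


class TestMonotonicity:
    def test_adding_sensor_never_decreases_metrics(self, rng):
        for seed in range(5):
            model = random_stable_lti(GeneratorSpec(n=4, spectral_radius=0.8,
                                                    seed=seed))
            A = model.matrices
            r = np.random.default_rng(seed)
            C1 = r.standard_normal((1, 4))
            C2 = np.vstack([C1, r.standard_normal((1, 4))])
            x0 = r.standard_normal(4)
            G1 = gramian_lyapunov(A, C1, "discrete")
            G2 = gramian_lyapunov(A, C2, "discrete")
            assert metric_energy(G2, x0) >= metric_energy(G1, x0) - 1e-12
            assert metric_visibility(G2) >= metric_visibility(G1) - 1e-12
            O1 = observability_matrix(A, C1)
            O2 = observability_matrix(A, C2)
            assert metric_rank(O2) >= metric_rank(O1)


class TestDuality:
    def test_observability_equals_dual_controllability(self, rng):
        """Go of (A, C) solves the same equation as the controllability
        Gramian of (A', C'), accumulated by an independent series."""
        for seed in range(4):
            model = random_stable_lti(GeneratorSpec(n=5, spectral_radius=0.8,
                                                    seed=seed + 20))
            A = model.matrices
            C = np.random.default_rng(seed).standard_normal((2, 5))
            Go = gramian_lyapunov(A, C, "discrete").Go
            # controllability Gramian of the dual pair, by direct series
            Ad, Bd = A.T, C.T
            Wc = np.zeros((5, 5))
            M = Bd.copy()
            for _ in range(600):
                Wc += M @ M.T
                M = Ad @ M
            assert np.max(np.abs(Go - Wc)) < 1e-8
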