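import math

import numpy as np
import pytest

from aneuqs.dynamics import (
    build_value_matrix,
    error_class_threshold_scan,
    error_class_transition_matrix,
    integrate_replicator_mutator,
    stationary_distribution,
    threshold_scan,
)
from aneuqs.fitness import FitnessAssignment, PopulationState, single_peak_landscape
from aneuqs.replication import ReplicationKernel, build_transition_matrix
from aneuqs.units import Karyotype, enumerate_karyotype_space


def _single_peak_system(e=0.05, n_units=1, max_copy=6, master_copies=3, A_master=4.0):
    space = enumerate_karyotype_space(n_units, max_copy)
    master = Karyotype((master_copies,) * n_units)
    f = single_peak_landscape(space, master, A_master, 1.0, lethal_on_nullisomy=False)
    Q, _ = build_transition_matrix(space, ReplicationKernel(e))
    return space, master, f, build_value_matrix(f, Q)


class TestBuildValueMatrix:
    def test_two_state_toy(self):
        f = FitnessAssignment(A=np.array([4.0, 1.0]), D=np.zeros(2))
        Q = np.array([[0.5, 0.0], [0.4, 1.0]])
        W = build_value_matrix(f, Q)
        assert W[0, 0] == pytest.approx(2.0)
        assert W[1, 0] == pytest.approx(1.6)

    def test_zero_error_is_diagonal_growth(self, small_space):
        f = single_peak_landscape(small_space, Karyotype((2, 2)), 3.0, 1.0)
        Q, _ = build_transition_matrix(small_space, ReplicationKernel(0.0))
        W = build_value_matrix(f, Q)
        assert np.allclose(W, np.diag(f.A))

    def test_diagonal_definition(self, small_space, kernel):
        f = single_peak_landscape(small_space, Karyotype((2, 2)), 3.0, 1.0, 0.25)
        Q, _ = build_transition_matrix(small_space, kernel)
        W = build_value_matrix(f, Q)
        assert np.allclose(np.diag(W), f.A * np.diag(Q) - f.D)

    def test_shape_mismatch(self):
        f = FitnessAssignment(A=np.ones(3), D=np.zeros(3))
        with pytest.raises(ValueError):
            build_value_matrix(f, np.eye(2))


class TestIntegrator:
    def test_simplex_conserved_along_trajectory(self):
        _, _, _, W = _single_peak_system(e=0.1)
        x0 = PopulationState(np.full(W.shape[0], 1.0 / W.shape[0]))
        traj = integrate_replicator_mutator(W, x0, t_end=50.0)
        sums = traj.states.sum(axis=1)
        assert np.abs(sums - 1.0).max() <= 1e-8
        assert (traj.states >= -1e-12).all()

    def test_stationary_point_is_fixed(self):
        _, _, _, W = _single_peak_system(e=0.08)
        xs = stationary_distribution(W)
        traj = integrate_replicator_mutator(W, xs, t_end=20.0)
        assert np.abs(traj.states - xs.x).max() <= 1e-8

    def test_competitive_exclusion_without_error(self):
        space, master, f, W = _single_peak_system(e=0.0)
        m = space.index(master)
        x0 = PopulationState(np.full(len(space), 1.0 / len(space)))
        traj = integrate_replicator_mutator(W, x0, t_end=500.0)
        assert traj.final.x[m] == pytest.approx(1.0, abs=1e-6)
        assert traj.residual <= 1e-8


class TestStationaryDistribution:
    def test_delta_on_master_without_error(self):
        space, master, _, W = _single_peak_system(e=0.0)
        x = stationary_distribution(W).x
        assert x[space.index(master)] == pytest.approx(1.0)

    def test_matches_long_time_ode_limit(self):
        _, _, _, W = _single_peak_system(e=0.12, max_copy=8, master_copies=4)
        xs = stationary_distribution(W).x
        x0 = PopulationState(np.full(W.shape[0], 1.0 / W.shape[0]))
        traj = integrate_replicator_mutator(W, x0, t_end=1000.0)
        tv = 0.5 * np.abs(traj.final.x - xs).sum()
        assert tv <= 1e-6

    def test_two_state_no_back_mutation_closed_form(self):
        sigma, Q = 10.0, 0.5
        W = np.array([[sigma * Q, 0.0], [sigma * (1 - Q), 1.0]])
        x = stationary_distribution(W).x
        assert x[0] == pytest.approx((sigma * Q - 1) / (sigma - 1), abs=1e-12)
        assert x[0] == pytest.approx(4.0 / 9.0, abs=1e-12)


class TestThresholdScanExactKernel:
    def test_master_frequency_one_at_zero_error(self):
        space = enumerate_karyotype_space(1, 8)
        master = Karyotype((4,))
        f = single_peak_landscape(space, master, math.e, 1.0, lethal_on_nullisomy=False)
        res = threshold_scan(space, f, master, np.linspace(0.0, 0.1, 5))
        assert res.master_freq[0] == pytest.approx(1.0)
        assert res.sigma_bar == pytest.approx(math.e)

    def test_master_frequency_non_increasing(self):
        space = enumerate_karyotype_space(1, 10)
        master = Karyotype((5,))
        f = single_peak_landscape(space, master, 4.0, 1.0, lethal_on_nullisomy=False)
        res = threshold_scan(space, f, master, np.linspace(0.01, 0.3, 12))
        assert (np.diff(res.master_freq) <= 1e-9).all()

    def test_grid_validation(self):
        space = enumerate_karyotype_space(1, 4)
        master = Karyotype((2,))
        f = single_peak_landscape(space, master, 2.0, 1.0)
        with pytest.raises(ValueError):
            threshold_scan(space, f, master, [0.2, 0.1])


class TestErrorClassModel:
    def test_columns_stochastic_and_master_diagonal_exact(self):
        for c, e in [(10, 0.05), (46, 0.02), (5, 0.3)]:
            Q = error_class_transition_matrix(c, e, n_classes=12)
            assert np.allclose(Q.sum(axis=0), 1.0, atol=1e-12)
            assert Q[0, 0] == pytest.approx((1 - e) ** c, rel=1e-12)
            assert np.tril(Q, -1).min() >= 0  # downward flux only plus lumped class

    def test_no_back_mutation(self):
        Q = error_class_transition_matrix(8, 0.1, n_classes=10)
        assert np.triu(Q, 1).max() == 0.0

    def test_detected_threshold_near_analytic_bound(self):
        # sigma = e so the analytic bound is 1/c
        res = error_class_threshold_scan(10, np.linspace(0.02, 0.25, 60), A_master=math.e)
        assert res.analytic_threshold == pytest.approx(0.1)
        assert res.detected_threshold is not None
        assert abs(res.detected_threshold - 0.1) / 0.1 <= 0.25

    def test_detection_approaches_bound_as_length_grows(self):
        rel = []
        for c in (10, 20, 46):
            grid = np.linspace(0.2 / c, 2.5 / c, 60)
            res = error_class_threshold_scan(c, grid, A_master=math.e)
            rel.append(abs(res.detected_threshold - res.analytic_threshold) / res.analytic_threshold)
        assert rel[-1] < rel[0]
        assert all(r <= 0.25 for r in rel)
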