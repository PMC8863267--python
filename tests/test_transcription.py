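"""Collocation transcription: objective, defects, bookkeeping, Jacobian."""

import math

import numpy as np
import pytest
import scipy.sparse as sp

from pedalsim.models import MuscleModel, TorqueModel
from pedalsim.transcription import (NLPProblem, ObjectiveWeights, TrackingTarget,
                                    Trajectory, boundary_constraints, build_nlp,
                                    color_columns, defect_constraints,
                                    fd_jacobian, jacobian_sparsity, objective,
                                    tracking_term)


class _ScalarOutputModel:
    """Stub whose single tracked output is the first state coordinate."""

    nx, nu = 1, 1
    crank_angle_index = 0

    def outputs(self, x):
        return np.array([x[0]])

    def effort(self, u):
        return float(np.sum(np.abs(u) ** 3))


class TestObjective:
    def test_two_node_hand_computed_value(self):
        """v=1, Y=(0,0), Yhat=(1,2), SD=1, w1=1, w2=0 -> (1+4)/2 = 2.5."""
        traj = Trajectory(1.0, np.array([[1.0], [2.0]]), np.zeros((2, 1)))
        target = TrackingTarget(np.zeros((2, 1)), np.ones((2, 1)), names=("y",))
        model = _ScalarOutputModel()
        j, jt, ja = objective(traj, target, ObjectiveWeights(1.0, 0.0), model)
        assert j == pytest.approx(2.5)
        assert jt == pytest.approx(2.5)

    def test_perfect_tracking_zero_activation_gives_zero(self):
        traj = Trajectory(1.0, np.array([[3.0], [4.0]]), np.zeros((2, 1)))
        target = TrackingTarget(np.array([[3.0], [4.0]]), np.ones((2, 1)),
                                names=("y",))
        j, jt, ja = objective(traj, target, ObjectiveWeights(1.0, 1.0),
                              _ScalarOutputModel())
        assert j == 0.0

    def test_zero_sd_rejected(self):
        with pytest.raises(ValueError, match="SD"):
            TrackingTarget(np.zeros((2, 1)), np.zeros((2, 1)))

    def test_weight_separability(self, torque_model, ref61):
        """J(w1, w2) = w1 J(1,0) + w2 J(0,1) at a fixed trajectory."""
        traj = ref61.trajectory
        tgt = ref61.target
        j10 = objective(traj, tgt, ObjectiveWeights(1, 0), torque_model)[0]
        j01 = objective(traj, tgt, ObjectiveWeights(0, 1), torque_model)[0]
        for w1, w2 in ((1.0, 0.5), (2.0, 3.0), (0.3, 10.0)):
            j = objective(traj, tgt, ObjectiveWeights(w1, w2), torque_model)[0]
            assert j == pytest.approx(w1 * j10 + w2 * j01, rel=1e-12)

    def test_w1_zero_leaves_pure_activation_term(self, torque_model, ref61):
        """The activation-only weighting isolates the effort term."""
        j, jt, ja = objective(ref61.trajectory, ref61.target,
                              ObjectiveWeights(0.0, 1.0), torque_model)
        assert j == pytest.approx(ja)
        assert ja > 0


class TestDefects:
    def test_scalar_backward_euler_exact_step(self):
        """x' = -x, dt = 0.1: x1 = x0/1.1 zeroes the backward-Euler defect."""
        traj = Trajectory(0.1, np.array([[1.0], [1.0 / 1.1]]), np.zeros((2, 1)))
        res = defect_constraints(traj, lambda x, u: -x)
        assert np.allclose(res, 0.0, atol=1e-15)

    def test_constant_states_zero_dynamics(self):
        traj = Trajectory(1.0, np.ones((5, 3)), np.zeros((5, 2)))
        res = defect_constraints(traj, lambda x, u: np.zeros(3))
        assert res.shape == (12,)
        assert np.allclose(res, 0.0)

    def test_residual_first_order_in_dt(self, cfg, ref61):
        """The defect of an exact model trajectory decays O(dt): halving dt
        roughly halves the residual (consistency order of backward Euler)."""
        from conftest import subsample_trajectory
        model = TorqueModel(cfg, ref61.profile)
        r_coarse = defect_constraints(subsample_trajectory(ref61.trajectory, 16),
                                      model.f)
        r_fine = defect_constraints(subsample_trajectory(ref61.trajectory, 31),
                                    model.f)
        ratio = np.max(np.abs(r_coarse)) / np.max(np.abs(r_fine))
        assert 1.4 < ratio < 2.9

    def test_non_finite_dynamics_reports_node(self):
        def bad(x, u):
            return np.full(3, np.nan)
        traj = Trajectory(1.0, np.ones((4, 3)), np.zeros((4, 1)))
        with pytest.raises(FloatingPointError, match="node 1"):
            defect_constraints(traj, bad)


class TestBoundary:
    def test_periodic_cycle_all_residuals_zero(self, cfg, ref61):
        traj = ref61.trajectory
        states = traj.states.copy()
        states[-1] = states[0]
        states[-1, 6] = 2 * math.pi
        states[0, 6] = 0.0
        controls = traj.controls.copy()
        controls[-1] = controls[0]
        res = boundary_constraints(Trajectory(traj.tFinal, states, controls))
        assert res.shape == (21,)   # (nx-1) + nu + 2 for the reduced model
        assert np.allclose(res, 0.0, atol=1e-12)

    def test_count_is_sixty_nine_for_full_model(self, cfg):
        n = 7
        traj = Trajectory(cfg.tFinal, np.zeros((n, 50)), np.zeros((n, 18)))
        assert boundary_constraints(traj).shape == (69,)

    def test_crank_rows_ignore_other_coordinates(self, cfg):
        rng = np.random.default_rng(0)
        states = rng.normal(size=(4, 50))
        traj = Trajectory(1.0, states, rng.normal(size=(4, 18)))
        res = boundary_constraints(traj)
        assert res[-2] == pytest.approx(states[0, 6])
        assert res[-1] == pytest.approx(states[-1, 6] - 2 * math.pi)


class TestBookkeeping:
    @pytest.mark.parametrize("n,n_dec,n_con", [
        (11, 748, 569), (31, 2108, 1569), (51, 3468, 2569),
        (91, 6188, 4569), (181, 12308, 9069)])
    def test_full_model_dimensions(self, cfg, n, n_dec, n_con):
        """68n unknowns and 50(n-1) + 68 + 1 equality constraints."""
        model = MuscleModel(cfg)
        tgt = TrackingTarget(np.zeros((n, 6)), np.ones((n, 6)))
        p = build_nlp(model, tgt, ObjectiveWeights(1, 1), n, cfg.tFinal)
        assert p.n_decision == n_dec
        assert p.n_constraints == n_con

    def test_node_spacing_endpoints(self, cfg):
        tgt = TrackingTarget(np.zeros((2, 6)), np.ones((2, 6)))
        model = MuscleModel(cfg)
        p11 = build_nlp(model, tgt, ObjectiveWeights(1, 1), 11, 1.914)
        p181 = build_nlp(model, tgt, ObjectiveWeights(1, 1), 181, 1.914)
        traj11 = Trajectory(1.914, np.zeros((11, 50)), np.zeros((11, 18)))
        traj181 = Trajectory(1.914, np.zeros((181, 50)), np.zeros((181, 18)))
        assert traj11.dt == pytest.approx(0.1914)
        assert round(traj181.dt, 4) == 0.0106
        assert p11.n == 11 and p181.n == 181

    def test_invalid_node_count_rejected(self, cfg):
        tgt = TrackingTarget(np.zeros((2, 6)), np.ones((2, 6)))
        with pytest.raises(ValueError):
            build_nlp(MuscleModel(cfg), tgt, ObjectiveWeights(1, 1), 1, 1.914)


class TestSparsity:
    def test_hand_enumerated_pattern_n3(self):
        """n=3 toy layout (nx=2, nu=1): two defect row blocks plus boundary."""
        pat = jacobian_sparsity(3, 2, 1, crank_index=0).toarray()
        nx, nu, blk = 2, 1, 3
        assert pat.shape == (2 * 2 + 1 + 1 + 2, 9)
        # defect block 0: diagonal on x_0, dense on (x_1, u_1)
        assert pat[0, 0] and not pat[0, 1]
        assert pat[1, 1] and not pat[1, 0]
        assert pat[0:2, 3:6].all()
        assert not pat[0:2, 6:9].any()
        # defect block 1: nodes 1 and 2 only
        assert not pat[2:4, 0:3].any()
        # boundary rows touch first/last node columns only
        assert not pat[4:, 3:6].any()

    def test_density_decays_with_n(self):
        d = []
        for n in (5, 10, 20, 40):
            pat = jacobian_sparsity(n, 14, 6, 6)
            d.append(pat.nnz / (pat.shape[0] * pat.shape[1]))
        assert d[0] > d[1] > d[2] > d[3]
        assert d[1] / d[3] > 3.0     # roughly O(1/n)

    def test_pattern_covers_dense_fd_jacobian(self, torque_model, ref61):
        """Every nonzero of a dense FD Jacobian lies inside the pattern."""
        from conftest import subsample_trajectory
        n = 4
        tgt = ref61.target.resample(n)
        p = build_nlp(torque_model, tgt, ObjectiveWeights(1, 1), n, ref61.tFinal)
        z = subsample_trajectory(ref61.trajectory, n).pack()
        c0 = p.constraints(z)
        dense = np.empty((p.n_constraints, p.n_decision))
        h = 1e-6
        for j in range(p.n_decision):
            zp = z.copy()
            zp[j] += h
            dense[:, j] = (p.constraints(zp) - c0) / h
        pat = p.pattern.toarray()
        outside = np.abs(dense[~pat])
        assert outside.max() < 1e-5 * max(1.0, np.abs(dense).max())


class TestColoredJacobian:
    def test_linear_constraints_recovered_exactly(self):
        rng = np.random.default_rng(4)
        A = rng.normal(size=(6, 8))
        mask = rng.random((6, 8)) < 0.4
        A = A * mask
        pat = sp.csc_matrix(mask)
        J = fd_jacobian(lambda z: A @ z, rng.normal(size=8), pat, rel_step=1e-7)
        assert np.max(np.abs(J.toarray() - A)) < 1e-7

    def test_grouped_equals_ungrouped_on_small_problem(self, torque_model, ref61):
        from conftest import subsample_trajectory
        n = 4
        p = build_nlp(torque_model, ref61.target, ObjectiveWeights(1, 1), n,
                      ref61.tFinal)
        z = subsample_trajectory(ref61.trajectory, n).pack()
        grouped = fd_jacobian(p.constraints, z, p.pattern, p.groups).toarray()
        singleton = [np.array([j]) for j in range(p.n_decision)]
        ungrouped = fd_jacobian(p.constraints, z, p.pattern, singleton).toarray()
        assert np.max(np.abs(grouped - ungrouped)) < 1e-10

    def test_evaluation_count_bounded_by_colors(self, torque_model, ref61):
        from conftest import subsample_trajectory
        p = build_nlp(torque_model, ref61.target, ObjectiveWeights(1, 1), 6,
                      ref61.tFinal)
        z = subsample_trajectory(ref61.trajectory, 6).pack()
        counter = [0]
        fd_jacobian(p.constraints, z, p.pattern, p.groups, counter=counter)
        assert counter[0] <= len(p.groups) + 1
        # far fewer evaluations than one per column
        assert len(p.groups) < p.n_decision / 2

    def test_coloring_is_structurally_orthogonal(self, torque_model, ref61):
        p = build_nlp(torque_model, ref61.target, ObjectiveWeights(1, 1), 8,
                      ref61.tFinal)
        pat = p.pattern.tocsc()
        for group in p.groups:
            seen = np.zeros(pat.shape[0], bool)
            for col in group:
                rows = pat.indices[pat.indptr[col]:pat.indptr[col + 1]]
                assert not seen[rows].any()
                seen[rows] = True


class TestGradient:
    def test_gradient_matches_finite_differences(self, torque_model, ref61):
        from conftest import subsample_trajectory
        p = build_nlp(torque_model, ref61.target, ObjectiveWeights(1.0, 2.0), 4,
                      ref61.tFinal)
        z = subsample_trajectory(ref61.trajectory, 4).pack()
        g = p.gradient(z)
        h = 1e-6
        idx = np.linspace(0, p.n_decision - 1, 25).astype(int)
        for j in idx:
            zp, zm = z.copy(), z.copy()
            zp[j] += h
            zm[j] -= h
            fd = (p.objective(zp) - p.objective(zm)) / (2 * h)
            assert g[j] == pytest.approx(fd, rel=2e-3, abs=1e-7)
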