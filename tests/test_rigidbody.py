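"""Rigid-body kinematics and dynamics checks against independent oracles."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from pedalsim import config as pcfg
from pedalsim import rigidbody as rb


def rot(a):
    return np.array([[math.cos(a), -math.sin(a)], [math.sin(a), math.cos(a)]])


@given(crank=st.floats(-10, 10))
def test_pedal_points_lie_on_crank_circle(cfg, crank):
    pts = rb.pedal_points(cfg, crank)
    for side in ("L", "R"):
        assert np.hypot(*pts[side]) == pytest.approx(cfg.crank_arm_length, abs=1e-12)
    # pedals are diametrically opposite
    assert np.allclose(pts["L"], -pts["R"])


def test_pedal_at_top_dead_center_for_zero_crank(cfg):
    pts = rb.pedal_points(cfg, 0.0)
    assert pts["L"] == pytest.approx([0.0, cfg.crank_arm_length])


def test_forward_kinematics_matches_hand_rotation_chain(cfg):
    """Toe/heel of a fixed posture vs an independently composed 2-D
    rotation chain (different formulation: explicit rotation matrices)."""
    qh, qk, qa = 0.6, 1.1, -0.3
    q = np.array([qh, qk, qa, 0.2, 0.4, 0.1, 1.0])
    pts = rb.forward_kinematics(cfg, q)

    H = cfg.hip_position
    down = np.array([0.0, -1.0])
    thigh_dir = rot(qh) @ down
    shank_dir = rot(qh - qk) @ down
    ankle = H + cfg.segments["thigh"].length * thigh_dir \
        + cfg.segments["shank"].length * shank_dir
    foot_dir = rot(qh - qk + qa) @ np.array([1.0, 0.0])
    toe = ankle + cfg.toe_from_ankle * foot_dir
    heel = ankle + cfg.heel_from_ankle * foot_dir

    assert np.allclose(pts["ankle_L"], ankle, atol=1e-12)
    assert np.allclose(pts["toe_L"], toe, atol=1e-12)
    assert np.allclose(pts["heel_L"], heel, atol=1e-12)


class TestPedalAngle:
    def test_horizontal_foot_is_zero_without_offset(self, cfg):
        # foot axis horizontal: chi = 0 requires qa = -(qh - qk)
        q = np.zeros(7)
        q[0], q[1] = 0.5, 1.0
        q[2] = -(q[0] - q[1])
        ang = rb.pedal_angle(cfg, q, apply_offset=False)
        assert ang["L"] == pytest.approx(0.0, abs=1e-12)

    def test_toe_below_heel_matches_arctangent_oracle(self, cfg):
        # foot pitched so the toe drops 0.05 m per 0.12 m horizontal run
        chi = math.atan2(-0.05, 0.12)
        q = np.zeros(7)
        q[0], q[1] = 0.5, 1.0
        q[2] = chi - (q[0] - q[1])
        expect = math.degrees(math.atan2(0.05, 0.12))
        ang = rb.pedal_angle(cfg, q, apply_offset=False)
        assert ang["L"] == pytest.approx(expect, abs=1e-9)
        with_off = rb.pedal_angle(cfg, q, apply_offset=True)
        assert with_off["L"] == pytest.approx(expect + cfg.pedal_angle_offset_deg,
                                              abs=1e-9)

    def test_degenerate_foot_raises(self, cfg):
        import dataclasses
        bad = dataclasses.replace(cfg, toe_from_ankle=0.0, heel_from_ankle=0.0)
        with pytest.raises(ValueError, match="toe"):
            rb.pedal_angle(bad, np.zeros(7))


class TestSprings:
    def test_zero_force_at_rest_length(self, cfg):
        # place the left metatarsal exactly on the left pedal point
        ped = rb.pedal_points(cfg, 0.7)["L"]
        qL = rb.leg_ik(cfg, ped, -0.1)
        q = np.concatenate([qL, qL, [0.7]])
        f_foot, f_pedal = rb.spring_forces(cfg, q)["L"]
        # IK is analytic; residual force is k times the IK placement error
        assert np.allclose(f_foot, 0.0, atol=1e-3)

    def test_hundred_newtons_per_millimeter(self, cfg):
        # k = 1e5 N/m and 1 mm of stretch -> 100 N along the line
        ped = rb.pedal_points(cfg, 0.7)["L"]
        qL = rb.leg_ik(cfg, ped + np.array([0.001, 0.0]), -0.1)
        q = np.concatenate([qL, qL, [0.7]])
        f_foot, f_pedal = rb.spring_forces(cfg, q)["L"]
        assert np.hypot(*f_foot) == pytest.approx(100.0, rel=1e-6)
        assert np.allclose(f_foot, -f_pedal)       # Newton's third law
        # foot displaced anteriorly -> anterior (positive x) pedal force
        assert f_pedal[0] == pytest.approx(100.0, rel=1e-6)

    def test_spring_work_equals_stored_energy(self, cfg):
        """Quasi-static displacement: line integral of spring force on the
        foot equals -(change of elastic energy 1/2 k d^2)."""
        ped = rb.pedal_points(cfg, 0.7)["L"]
        path = np.linspace(0.0, 0.004, 200)
        work = 0.0
        prev_pos = None
        for i, d in enumerate(path):
            qL = rb.leg_ik(cfg, ped + np.array([d, 0.0]), -0.1)
            q = np.concatenate([qL, qL, [0.7]])
            f_foot, _ = rb.spring_forces(cfg, q)["L"]
            pos = rb.leg_kinematics(cfg, qL).points["meta"].pos
            if prev_pos is not None:
                work += float(f_mid @ (pos - prev_pos))
            prev_pos, f_mid = pos, f_foot
        stored = 0.5 * cfg.spring_k * path[-1] ** 2
        assert work == pytest.approx(-stored, rel=2e-2)


class TestDynamics:
    def test_zero_forces_zero_acceleration(self, cfg):
        q = np.array([0.5, 1.0, -0.2, 0.6, 1.2, 0.1, 0.3])
        qdd = rb.forward_dynamics(cfg, q, np.zeros(7), include_springs=False,
                                  gravity_on=False)
        assert np.allclose(qdd, 0.0, atol=1e-12)

    def test_compound_pendulum_closed_form(self, cfg):
        """Thigh alone (massless shank/foot) behaves as a compound pendulum:
        alpha = -m g c sin(theta) / (I + m c^2)."""
        import copy
        light = copy.deepcopy(cfg)
        light.segments["shank"] = pcfg.SegmentParams("shank", 1e-9, 0.42, 0.18, 0.0)
        light.segments["foot"] = pcfg.SegmentParams("foot", 1e-9, 0.24, 0.12, 0.0)
        th = 0.7
        q = np.array([th, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0])
        qdd = rb.forward_dynamics(light, q, np.zeros(7), include_springs=False)
        p = light.segments["thigh"]
        expect = -p.mass * light.gravity * p.com_offset * math.sin(th) / (
            p.inertia_com + p.mass * p.com_offset ** 2)
        assert qdd[0] == pytest.approx(expect, rel=1e-6)

    def test_crank_acceleration_is_torque_over_inertia(self, cfg):
        """Constant torque T on the lumped crank: alpha = T / I_eff
        (resistive torque sign opposes positive rotation)."""
        q = np.array([0.5, 1.0, -0.2, 0.6, 1.2, 0.1, 0.3])
        T = 10.0
        qdd = rb.forward_dynamics(cfg, q, np.zeros(7), resistive_torque=-T,
                                  include_springs=False, gravity_on=False)
        assert qdd[6] == pytest.approx(T / cfg.crank_inertia_eff, rel=1e-12)
        assert qdd[6] == pytest.approx(T / 23.53, rel=1e-12)

    def test_mass_matrix_symmetric_positive_definite(self, cfg):
        rng = np.random.default_rng(11)
        for _ in range(100):
            q = rng.uniform(-1.0, 2.5, 7)
            M = rb.mass_matrix(cfg, q)
            assert np.allclose(M, M.T, atol=1e-12)
            assert np.linalg.eigvalsh(M).min() > 0

    def test_energy_conservation_passive_swing(self, cfg):
        """Springs and muscles disabled: total mechanical energy conserved
        to 1e-6 relative over one simulated second."""
        x0 = np.concatenate([[0.5, 1.0, -0.2, 0.9, 1.4, 0.1, 0.0],
                             [1.0, -0.5, 2.0, -1.0, 0.5, 1.0, 2.0]])

        def rhs(t, x):
            qdd = rb.forward_dynamics(cfg, x[:7], x[7:], include_springs=False)
            return np.concatenate([x[7:], qdd])

        sol = solve_ivp(rhs, (0.0, 1.0), x0, method="DOP853",
                        rtol=1e-11, atol=1e-12, dense_output=True)
        assert sol.success

        def energy(x):
            return (rb.kinetic_energy(cfg, x[:7], x[7:])
                    + rb.potential_energy(cfg, x[:7]))

        e0 = energy(x0)
        scale = max(abs(e0), rb.kinetic_energy(cfg, x0[:7], x0[7:]))
        for t in np.linspace(0.0, 1.0, 11):
            assert abs(energy(sol.sol(t)) - e0) <= 1e-6 * scale


class TestJacobians:
    def test_point_jacobians_match_finite_differences(self, cfg):
        rng = np.random.default_rng(5)
        h = 1e-7
        for _ in range(10):
            q3 = rng.uniform([-0.3, 0.1, -0.8], [2.0, 2.5, 0.8])
            leg = rb.leg_kinematics(cfg, q3)
            for name, pk in leg.points.items():
                jfd = np.empty((2, 3))
                for i in range(3):
                    qp, qm = q3.copy(), q3.copy()
                    qp[i] += h
                    qm[i] -= h
                    jfd[:, i] = (rb.leg_kinematics(cfg, qp).points[name].pos
                                 - rb.leg_kinematics(cfg, qm).points[name].pos) / (2 * h)
                assert np.allclose(jfd, pk.jac, atol=1e-6), name

    def test_analytic_velocities_match_numerical_differentiation(self, cfg):
        """d(point)/dt from the analytic Jacobian vs numerical
        differentiation of positions along a trajectory (1e-6 relative)."""
        q3 = np.array([0.7, 1.2, -0.2])
        qd3 = np.array([1.3, -0.8, 2.0])
        h = 1e-7
        leg = rb.leg_kinematics(cfg, q3, qd3)
        for name, pk in leg.points.items():
            v_analytic = pk.jac @ qd3
            v_fd = (rb.leg_kinematics(cfg, q3 + h * qd3).points[name].pos
                    - rb.leg_kinematics(cfg, q3 - h * qd3).points[name].pos) / (2 * h)
            assert np.allclose(v_analytic, v_fd, rtol=1e-6, atol=1e-9), name

    def test_knee_coupling_jacobians_consistent(self, cfg):
        """Optional knee joint-center translation: analytic Jacobians and
        Jdot*qdot still match finite differences."""
        import copy
        coupled = copy.deepcopy(cfg)
        coupled.knee_coupling = {"x": [0.0, 0.01, -0.002], "y": [0.0, 0.005]}
        rng = np.random.default_rng(8)
        h = 1e-6
        for _ in range(5):
            q3 = rng.uniform([-0.3, 0.1, -0.8], [2.0, 2.5, 0.8])
            qd3 = rng.normal(0.0, 2.0, 3)
            leg = rb.leg_kinematics(coupled, q3, qd3)
            for name, pk in leg.points.items():
                jfd = np.empty((2, 3))
                for i in range(3):
                    qp, qm = q3.copy(), q3.copy()
                    qp[i] += h
                    qm[i] -= h
                    jfd[:, i] = (rb.leg_kinematics(coupled, qp).points[name].pos
                                 - rb.leg_kinematics(coupled, qm).points[name].pos) / (2 * h)
                assert np.allclose(jfd, pk.jac, atol=1e-5), name
                jp = rb.leg_kinematics(coupled, q3 + h * qd3).points[name].jac
                jm = rb.leg_kinematics(coupled, q3 - h * qd3).points[name].jac
                jd = (jp - jm) / (2 * h) @ qd3
                assert np.allclose(jd, pk.jdot_qdot, atol=1e-4), name


def test_leg_ik_round_trip_and_reach_error(cfg):
    for th in np.linspace(0.0, 2 * math.pi, 13):
        ped = rb.pedal_points(cfg, th)["L"]
        qL = rb.leg_ik(cfg, ped, -0.2)
        meta = rb.leg_kinematics(cfg, qL).points["meta"].pos
        assert np.allclose(meta, ped, atol=1e-9)
    with pytest.raises(ValueError, match="reach"):
        rb.leg_ik(cfg, np.array([2.0, -2.0]), 0.0)
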