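"""State-space dynamics models used by the collocation transcription.

Two model flavours share the same rigid-body core and tracked outputs:

* :class:`MuscleModel` — the full model: 50 states (7 joint angles, 7
  angular velocities, 18 muscle activations, 18 CC lengths) and 18
  excitation controls;
* :class:`TorqueModel` — a reduced, torque-actuated variant: 14 states
  (angles and velocities only) driven directly by the 6 joint torques.
  Useful for fast solves and for isolating skeletal dynamics from muscle
  dynamics.

Tracked outputs (6): left/right pedal angle (deg), left Fx, left Fy,
right Fx, right Fy (N, anterior/upward positive).
"""

from __future__ import annotations

import numpy as np

from . import muscle, rigidbody
from .config import CRANK_INDEX, N_MUS, N_Q, N_STATES, LEG_JOINTS, ModelConfig
from .crankload import ResistiveTorqueProfile, resistive_torque_at

OUTPUT_NAMES = ("pedal_angle_L", "pedal_angle_R",
                "pedal_force_x_L", "pedal_force_y_L",
                "pedal_force_x_R", "pedal_force_y_R")
N_OUTPUTS = len(OUTPUT_NAMES)


def profile_from_config(cfg: ModelConfig) -> ResistiveTorqueProfile:
    rp = cfg.resistive_profile
    if not rp:
        return ResistiveTorqueProfile()
    return ResistiveTorqueProfile(np.asarray(rp["angles_deg"], float),
                                  np.asarray(rp["torques_nm"], float))


def tracked_outputs(cfg: ModelConfig, q) -> np.ndarray:
    """Evaluate the 6 tracked pedal variables at posture ``q``.

    Single-pass evaluation of pedal angle and spring reaction force per
    leg (consistent with :func:`rigidbody.pedal_angle` and
    :func:`rigidbody.pedal_force`)."""
    import math

    q = np.asarray(q, float)
    ped = rigidbody.pedal_points(cfg, q[CRANK_INDEX])
    out = np.empty(N_OUTPUTS)
    for k, (side, sl) in enumerate((("L", slice(0, 3)), ("R", slice(3, 6)))):
        leg = rigidbody.leg_kinematics(cfg, q[sl])
        d = leg.points["toe"].pos - leg.points["heel"].pos
        out[k] = -math.degrees(math.atan2(d[1], d[0])) + cfg.pedal_angle_offset_deg
        delta = leg.points["meta"].pos - ped[side]
        d0 = cfg.spring_rest_length
        if d0 == 0.0:
            f_pedal = cfg.spring_k * delta
        else:
            dist = float(np.hypot(*delta))
            f_pedal = (cfg.spring_k * (dist - d0) * delta / dist
                       if dist > 1e-12 else np.zeros(2))
        out[2 + 2 * k] = f_pedal[0]
        out[3 + 2 * k] = f_pedal[1]
    return out


class _ModelBase:
    """Shared surface: bounds, output evaluation, crank bookkeeping."""

    def __init__(self, cfg: ModelConfig, profile: ResistiveTorqueProfile | None = None):
        self.cfg = cfg
        self.profile = profile if profile is not None else profile_from_config(cfg)

    # q occupies the first N_Q states in both flavours
    crank_angle_index = CRANK_INDEX
    crank_rate_index = N_Q + CRANK_INDEX

    def outputs(self, x) -> np.ndarray:
        return tracked_outputs(self.cfg, np.asarray(x, float)[:N_Q])

    def _q_bounds(self):
        lo, hi = np.empty(N_Q), np.empty(N_Q)
        ab = self.cfg.angle_bounds
        for i, joint in enumerate(LEG_JOINTS * 2):
            lo[i], hi[i] = ab.get(joint, (-np.pi, np.pi))
        lo[CRANK_INDEX], hi[CRANK_INDEX] = ab.get("crank", (-1.0, 2 * np.pi + 1.0))
        return lo, hi

    def _qdot_bounds(self):
        v = self.cfg.velocity_bound
        return -v * np.ones(N_Q), v * np.ones(N_Q)

    def resistive(self, crank_angle: float) -> float:
        return float(resistive_torque_at(self.profile, crank_angle))


class TorqueModel(_ModelBase):
    """Torque-actuated reduced model: x = [q, qdot], u = 6 joint torques."""

    nx = 2 * N_Q
    nu = 6

    def f(self, x, u) -> np.ndarray:
        x = np.asarray(x, float)
        q, qdot = x[:N_Q], x[N_Q:]
        qddot = rigidbody.forward_dynamics(
            self.cfg, q, qdot, joint_torques=np.asarray(u, float),
            resistive_torque=self.resistive(q[CRANK_INDEX]))
        return np.concatenate([qdot, qddot])

    def state_bounds(self):
        qlo, qhi = self._q_bounds()
        vlo, vhi = self._qdot_bounds()
        return np.concatenate([qlo, vlo]), np.concatenate([qhi, vhi])

    def control_bounds(self):
        b = self.cfg.torque_bound
        return -b * np.ones(self.nu), b * np.ones(self.nu)

    def effort(self, u) -> float:
        """Cubed normalized joint torque (effort analogue of activation^3)."""
        return float(np.sum(np.abs(np.asarray(u, float) / self.cfg.torque_scale) ** 3))


class MuscleModel(_ModelBase):
    """Full muscle-driven model: x = [q, qdot, a(18), lcc(18)], u = excitations.

    Muscle curve evaluations are vectorized across the 18 MTUs (verified
    against the scalar reference functions in :mod:`pedalsim.muscle`).
    """

    nx = N_STATES
    nu = N_MUS

    def __init__(self, cfg: ModelConfig, profile=None):
        super().__init__(cfg, profile)
        self._build_tables()

    def _build_tables(self) -> None:
        from .config import LEG_JOINTS
        m = self.cfg.mtus
        self.fmax = np.array([p.fmax for p in m])
        self.lcc_opt = np.array([p.lcc_opt for p in m])
        self.slack = np.array([p.l_slack_sec for p in m])
        self.vmax = np.array([p.vmax for p in m])
        self.act_tau = np.array([p.act_tau for p in m])
        self.deact_tau = np.array([p.deact_tau for p in m])
        self.fv_shape = np.array([p.fv_shape for p in m])
        self.ecc_plateau = np.array([p.ecc_plateau for p in m])
        self.fl_width = np.array([p.fl_width for p in m])
        self.sec_ref = np.array([p.sec_strain_ref for p in m]) * np.maximum(self.slack, 1e-9)
        self.pec_width = np.array([p.pec_norm_width for p in m])
        self.l_ref = np.array([p.l_ref for p in m])
        # path terms: (mtu index, q index, torque index, coeffs, anticoeffs, theta_ref)
        self._terms = []
        for i, p in enumerate(m):
            base = 0 if p.side == "L" else 3
            for joint, coeffs in p.arms.items():
                c = np.asarray(coeffs, float)
                anti = np.polynomial.polynomial.polyint(c)
                ji = base + LEG_JOINTS.index(joint)
                self._terms.append((i, ji, c, anti, float(p.q_ref.get(joint, 0.0))))

    def lengths_and_torques(self, q, lcc):
        """MTU lengths and the 6 muscle joint torques, vectorized."""
        P = np.polynomial.polynomial
        lengths = self.l_ref.copy()
        tendon = np.zeros(N_MUS)
        tau = np.zeros(6)
        arms = []
        for (i, ji, c, anti, th0) in self._terms:
            th = q[ji]
            lengths[i] -= float(P.polyval(th, anti) - P.polyval(th0, anti))
            arms.append((i, ji, float(P.polyval(th, c))))
        stretch = np.maximum(lengths - lcc - self.slack, 0.0)
        tendon = self.fmax * (stretch / self.sec_ref) ** 2
        for (i, ji, r) in arms:
            tau[ji] += tendon[i] * r
        return lengths, tendon, tau

    def split(self, x):
        x = np.asarray(x, float)
        return (x[:N_Q], x[N_Q:2 * N_Q],
                x[2 * N_Q:2 * N_Q + N_MUS], x[2 * N_Q + N_MUS:])

    def _contraction_rates(self, act, lcc, lengths, tendon):
        lnorm = lcc / self.lcc_opt
        f_pec = self.fmax * np.maximum(lnorm - 1.0, 0.0) ** 2 / self.pec_width ** 2
        fl = np.maximum(np.exp(-(((lnorm - 1.0) / self.fl_width) ** 2)), 1e-3)
        denom = np.maximum(act, 1e-3) * self.fmax * fl
        scale = (tendon - f_pec) / denom
        a = self.fv_shape
        c = (self.ecc_plateau - 1.0) * a / (a + 1.0)
        v_short = a * (scale - 1.0) / (a + scale)
        with np.errstate(divide="ignore", invalid="ignore"):
            v_ecc = c * (scale - 1.0) / (self.ecc_plateau - scale)
        v = np.where(scale <= 1.0, v_short, v_ecc)
        v = np.where(scale <= 0.0, -1.0, v)
        v = np.where(scale >= self.ecc_plateau, 1.0, v)
        v = np.clip(v, -1.0, 1.0)
        return v * self.vmax * self.lcc_opt

    def f(self, x, u) -> np.ndarray:
        q, qdot, act, lcc = self.split(x)
        u = np.asarray(u, float)
        lengths, tendon, tau = self.lengths_and_torques(q, lcc)
        qddot = rigidbody.forward_dynamics(
            self.cfg, q, qdot, joint_torques=tau,
            resistive_torque=self.resistive(q[CRANK_INDEX]))
        adot = (u - act) / np.where(u >= act, self.act_tau, self.deact_tau)
        lccdot = self._contraction_rates(act, lcc, lengths, tendon)
        out = np.concatenate([qdot, qddot, adot, lccdot])
        if not np.all(np.isfinite(out)):
            raise FloatingPointError("non-finite state derivative")
        return out

    def state_bounds(self):
        qlo, qhi = self._q_bounds()
        vlo, vhi = self._qdot_bounds()
        alo, ahi = np.zeros(N_MUS), np.ones(N_MUS)
        llo = np.array([0.4 * m.lcc_opt for m in self.cfg.mtus])
        lhi = np.array([1.6 * m.lcc_opt for m in self.cfg.mtus])
        return (np.concatenate([qlo, vlo, alo, llo]),
                np.concatenate([qhi, vhi, ahi, lhi]))

    def control_bounds(self):
        return np.zeros(self.nu), np.ones(self.nu)

    def effort(self, u) -> float:
        # for the muscle model the effort term uses activations (states),
        # handled by the transcription; controls carry no direct cost
        return 0.0
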