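"""Planar multibody kinematics and dynamics of the bicycle-rider system.

Generalized coordinates (radians)::

    q = [hip_L, knee_L, ankle_L, hip_R, knee_R, ankle_R, crank]

Hip and knee angles are flexion-positive (hip measured from the downward
vertical, thigh swinging anteriorly positive; knee flexion folds the shank
posteriorly).  Ankle is dorsiflexion-positive with the neutral foot
perpendicular to the shank, toes anterior.  The crank angle is zero with the
left pedal at top dead center and increases counterclockwise in the
(x anterior, y up) frame.

Pelvis center and crank axis are fixed in space (seated pedaling); the two
legs are independent 3-DOF chains hanging from a shared hip point, coupled
to the crank only through the stiff foot-pedal springs.  The crank's
rotational inertia is the lumped effective flywheel inertia I_eff.

The optional knee joint-center coupling (2-D translation of the knee center
as polynomials in knee flexion angle) is applied in the thigh frame and
propagated to all distal points and Jacobians.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .config import CRANK_INDEX, N_Q, ModelConfig

_G_THIGH = np.array([1.0, 0.0, 0.0])
_G_SHANK = np.array([1.0, -1.0, 0.0])
_G_FOOT = np.array([1.0, -1.0, 1.0])
_G_KNEE = np.array([0.0, 1.0, 0.0])


def _u(phi: float) -> np.ndarray:
    """Unit vector along a segment whose absolute angle from the downward
    vertical is phi (CCW positive)."""
    return np.array([math.sin(phi), -math.cos(phi)])


def _up(phi: float) -> np.ndarray:
    return np.array([math.cos(phi), math.sin(phi)])


def _w(chi: float) -> np.ndarray:
    """Unit vector along the foot axis; chi measured from +x (anterior)."""
    return np.array([math.cos(chi), math.sin(chi)])


def _wp(chi: float) -> np.ndarray:
    return np.array([-math.sin(chi), math.cos(chi)])


@dataclass
class PointKin:
    """Position, 3-column Jacobian and Jdot*qdot of one point on a leg."""

    pos: np.ndarray
    jac: np.ndarray                      # 2 x 3, w.r.t. that leg's [hip, knee, ankle]
    jdot_qdot: np.ndarray | None = None  # 2, only when qdot supplied


@dataclass
class LegKin:
    """Kinematics of one leg chain at a given configuration."""

    points: dict = field(default_factory=dict)   # name -> PointKin
    ang_grad: dict = field(default_factory=dict) # segment -> d(abs angle)/dq row


def leg_kinematics(cfg: ModelConfig, q3, qdot3=None) -> LegKin:
    """Positions, Jacobians and (optionally) Jdot*qdot terms for one leg.

    ``q3 = [hip, knee, ankle]``.  Points computed: knee, ankle, toe, heel,
    meta (spring attachment), thigh_com, shank_com, foot_com.
    """
    if not cfg.knee_coupling:
        return _leg_kinematics_hinge(cfg, q3, qdot3)
    return _leg_kinematics_generic(cfg, q3, qdot3)


def _leg_kinematics_hinge(cfg: ModelConfig, q3, qdot3=None) -> LegKin:
    """Fast path for the pure-hinge knee (no joint-center coupling)."""
    qh, qk, qa = float(q3[0]), float(q3[1]), float(q3[2])
    phi_t = qh
    phi_s = qh - qk
    chi = phi_s + qa

    hx, hy = cfg.hip_position
    Lt = cfg.segments["thigh"].length
    ct = cfg.segments["thigh"].com_offset
    Ls = cfg.segments["shank"].length
    cs = cfg.segments["shank"].com_offset

    st, ct_ = math.sin(phi_t), math.cos(phi_t)
    ss, cs_ = math.sin(phi_s), math.cos(phi_s)
    sf, cf_ = math.sin(chi), math.cos(chi)
    # basis vectors: u = (sin, -cos) along segment, u' = (cos, sin);
    # foot: w = (cos, sin), w' = (-sin, cos)
    u_t = (st, -ct_)
    up_t = (ct_, st)
    u_s = (ss, -cs_)
    up_s = (cs_, ss)
    w_f = (cf_, sf)
    wp_f = (-sf, cf_)

    have_v = qdot3 is not None
    if have_v:
        om_t = float(qdot3[0])
        om_s = float(qdot3[0]) - float(qdot3[1])
        om_f = om_s + float(qdot3[2])
        om_t2, om_s2, om_f2 = om_t * om_t, om_s * om_s, om_f * om_f

    def make(a_t, a_s, a_f):
        # point = H + a_t*u_t [+ a_s*u_s [+ a_f*w_f]]
        px = hx + a_t * u_t[0]
        py = hy + a_t * u_t[1]
        jac = np.zeros((2, 3))
        jac[0, 0] = a_t * up_t[0]
        jac[1, 0] = a_t * up_t[1]
        if have_v:
            ax = -a_t * u_t[0] * om_t2
            ay = -a_t * u_t[1] * om_t2
        if a_s is not None:
            px += a_s * u_s[0]
            py += a_s * u_s[1]
            jac[0, 0] += a_s * up_s[0]
            jac[1, 0] += a_s * up_s[1]
            jac[0, 1] = -a_s * up_s[0]
            jac[1, 1] = -a_s * up_s[1]
            if have_v:
                ax -= a_s * u_s[0] * om_s2
                ay -= a_s * u_s[1] * om_s2
        if a_f is not None:
            px += a_f * w_f[0]
            py += a_f * w_f[1]
            jac[0, 0] += a_f * wp_f[0]
            jac[1, 0] += a_f * wp_f[1]
            jac[0, 1] -= a_f * wp_f[0]
            jac[1, 1] -= a_f * wp_f[1]
            jac[0, 2] = a_f * wp_f[0]
            jac[1, 2] = a_f * wp_f[1]
            if have_v:
                ax -= a_f * w_f[0] * om_f2
                ay -= a_f * w_f[1] * om_f2
        acc = np.array([ax, ay]) if have_v else None
        return PointKin(np.array([px, py]), jac, acc)

    leg = LegKin()
    leg.points["thigh_com"] = make(ct, None, None)
    leg.points["knee"] = make(Lt, None, None)
    leg.points["shank_com"] = make(Lt, cs, None)
    leg.points["ankle"] = make(Lt, Ls, None)
    leg.points["toe"] = make(Lt, Ls, cfg.toe_from_ankle)
    leg.points["heel"] = make(Lt, Ls, cfg.heel_from_ankle)
    leg.points["meta"] = make(Lt, Ls, cfg.meta_from_ankle)
    leg.points["foot_com"] = make(Lt, Ls, cfg.foot_com_from_ankle)
    leg.ang_grad = {"thigh": _G_THIGH, "shank": _G_SHANK, "foot": _G_FOOT}
    return leg


def _leg_kinematics_generic(cfg: ModelConfig, q3, qdot3=None) -> LegKin:
    qh, qk, qa = float(q3[0]), float(q3[1]), float(q3[2])
    phi_t = qh
    phi_s = qh - qk
    chi = phi_s + qa

    H = cfg.hip_position
    Lt = cfg.segments["thigh"].length
    ct = cfg.segments["thigh"].com_offset
    Ls = cfg.segments["shank"].length
    cs = cfg.segments["shank"].com_offset

    u_t, up_t = _u(phi_t), _up(phi_t)
    u_s, up_s = _u(phi_s), _up(phi_s)
    w_f, wp_f = _w(chi), _wp(chi)

    have_v = qdot3 is not None
    if have_v:
        om_t = float(np.dot(_G_THIGH, qdot3))
        om_s = float(np.dot(_G_SHANK, qdot3))
        om_f = float(np.dot(_G_FOOT, qdot3))
        om_k = float(np.dot(_G_KNEE, qdot3))

    # knee joint-center coupling offset, expressed in the thigh frame
    # basis (e1 = up_t along-axis-normal, e2 = -u_t) as polynomials in qk
    off = np.zeros(2)
    j_off = np.zeros((2, 3))
    a_off = np.zeros(2)
    if cfg.knee_coupling:
        cx = np.asarray(cfg.knee_coupling.get("x", [0.0]), float)
        cy = np.asarray(cfg.knee_coupling.get("y", [0.0]), float)
        ox = float(np.polynomial.polynomial.polyval(qk, cx))
        oy = float(np.polynomial.polynomial.polyval(qk, cy))
        oxp = float(np.polynomial.polynomial.polyval(qk, np.polynomial.polynomial.polyder(cx)))
        oyp = float(np.polynomial.polynomial.polyval(qk, np.polynomial.polynomial.polyder(cy)))
        e1, e2 = up_t, -u_t
        de1, de2 = -u_t, -up_t          # d/dphi_t
        off = ox * e1 + oy * e2
        j_off = (np.outer(ox * de1 + oy * de2, _G_THIGH)
                 + np.outer(oxp * e1 + oyp * e2, _G_KNEE))
        if have_v:
            oxpp = float(np.polynomial.polynomial.polyval(
                qk, np.polynomial.polynomial.polyder(cx, 2)))
            oypp = float(np.polynomial.polynomial.polyval(
                qk, np.polynomial.polynomial.polyder(cy, 2)))
            # d^2/dt^2 of f(qk)*b(phi_t) terms with qddot = 0
            a_off = ((oxpp * e1 + oypp * e2) * om_k ** 2
                     + 2.0 * (oxp * de1 + oyp * de2) * om_k * om_t
                     + (ox * -e1 + oy * -e2) * om_t ** 2)

    def chain_point(terms):
        """Build a PointKin from (amp, basis, dbasis, grad, omega) terms."""
        pos = H.copy()
        jac = np.zeros((2, 3))
        acc = np.zeros(2)
        for amp, b, db, g, om in terms:
            pos = pos + amp * b
            jac = jac + np.outer(amp * db, g)
            if have_v:
                acc = acc - amp * b * om * om    # b'' = -b for u and w
        return pos, jac, acc

    om_t_ = om_t if have_v else 0.0
    om_s_ = om_s if have_v else 0.0
    om_f_ = om_f if have_v else 0.0

    t_thigh = (Lt, u_t, up_t, _G_THIGH, om_t_)
    t_shank_full = (Ls, u_s, up_s, _G_SHANK, om_s_)

    def distal(terms, foot_dist=None):
        pos, jac, acc = chain_point(terms)
        pos = pos + off
        jac = jac + j_off
        if have_v:
            acc = acc + a_off
        if foot_dist is not None:
            pos = pos + foot_dist * w_f
            jac = jac + np.outer(foot_dist * wp_f, _G_FOOT)
            if have_v:
                acc = acc - foot_dist * w_f * om_f_ ** 2
        return PointKin(pos, jac, acc if have_v else None)

    leg = LegKin()
    leg.points["thigh_com"] = PointKin(*chain_point([(ct, u_t, up_t, _G_THIGH, om_t_)]))
    pk = chain_point([t_thigh])
    leg.points["knee"] = PointKin(pk[0] + off, pk[1] + j_off,
                                  (pk[2] + a_off) if have_v else None)
    leg.points["shank_com"] = distal([t_thigh, (cs, u_s, up_s, _G_SHANK, om_s_)])
    leg.points["ankle"] = distal([t_thigh, t_shank_full])
    for name, dist in (("toe", cfg.toe_from_ankle), ("heel", cfg.heel_from_ankle),
                       ("meta", cfg.meta_from_ankle), ("foot_com", cfg.foot_com_from_ankle)):
        leg.points[name] = distal([t_thigh, t_shank_full], foot_dist=dist)

    leg.ang_grad = {"thigh": _G_THIGH, "shank": _G_SHANK, "foot": _G_FOOT}
    return leg


# -- crank ---------------------------------------------------------------------

def pedal_points(cfg: ModelConfig, crank_angle: float):
    """World positions of the left and right pedal (spring) points.

    Left pedal at top dead center for crank angle 0; the right pedal is
    diametrically opposite (180 degrees out of phase).  Positive crank
    rotation carries the pedal through the anterior side on the downstroke
    (the positive/counterclockwise convention viewed from the rider's
    right).
    """
    r = cfg.crank_arm_length
    c, s = math.cos(crank_angle), math.sin(crank_angle)
    left = np.array([r * s, r * c])
    return {"L": left, "R": -left}


def pedal_point_jacobian(cfg: ModelConfig, crank_angle: float):
    """d(pedal point)/d(crank angle) per side."""
    r = cfg.crank_arm_length
    c, s = math.cos(crank_angle), math.sin(crank_angle)
    left = np.array([r * c, -r * s])
    return {"L": left, "R": -left}


def forward_kinematics(cfg: ModelConfig, q) -> dict:
    """Planar coordinates of every joint and attachment point.

    Returns a dict keyed ``hip``, ``crank_axis``, ``pedal_L/R`` and, per
    side, ``knee_L``, ``ankle_L``, ``toe_L``, ``heel_L``, ``meta_L`` etc.
    """
    q = np.asarray(q, float)
    pts = {"hip": cfg.hip_position, "crank_axis": np.zeros(2)}
    ped = pedal_points(cfg, q[CRANK_INDEX])
    pts["pedal_L"], pts["pedal_R"] = ped["L"], ped["R"]
    for side, sl in (("L", slice(0, 3)), ("R", slice(3, 6))):
        leg = leg_kinematics(cfg, q[sl])
        for name in ("knee", "ankle", "toe", "heel", "meta"):
            pts[f"{name}_{side}"] = leg.points[name].pos
    return pts


# -- pedal angle ---------------------------------------------------------------

def pedal_angle(cfg: ModelConfig, q, apply_offset: bool = True) -> dict:
    """Pedal angle per leg, degrees, from the toe-to-heel line.

    Positive when the toe lies below the horizontal through the heel
    (toe-down).  The reporting offset ``pedal_angle_offset_deg`` is added
    when ``apply_offset`` is true.
    """
    q = np.asarray(q, float)
    out = {}
    for side, sl in (("L", slice(0, 3)), ("R", slice(3, 6))):
        leg = leg_kinematics(cfg, q[sl])
        toe = leg.points["toe"].pos
        heel = leg.points["heel"].pos
        d = toe - heel
        if np.hypot(*d) < 1e-12:
            raise ValueError("degenerate foot geometry: toe coincides with heel")
        chi = math.atan2(d[1], d[0])
        ang = -math.degrees(chi)
        if apply_offset:
            ang += cfg.pedal_angle_offset_deg
        out[side] = ang
    return out


# -- springs -------------------------------------------------------------------

def spring_forces(cfg: ModelConfig, q, qdot=None) -> dict:
    """Foot-pedal coupling forces per side.

    Returns ``{side: (force_on_foot, force_on_pedal)}``; the two are equal
    and opposite.  Force magnitude is k*(d - d0) along the line from the
    metatarsal attachment to the pedal point, plus optional linear damping
    on the relative velocity.
    """
    q = np.asarray(q, float)
    ped = pedal_points(cfg, q[CRANK_INDEX])
    ped_j = pedal_point_jacobian(cfg, q[CRANK_INDEX])
    out = {}
    for side, sl in (("L", slice(0, 3)), ("R", slice(3, 6))):
        leg = leg_kinematics(cfg, q[sl])
        pf = leg.points["meta"].pos
        delta = pf - ped[side]
        d = float(np.hypot(*delta))
        d0 = cfg.spring_rest_length
        if d0 == 0.0:
            f_foot = -cfg.spring_k * delta
        elif d > 1e-12:
            f_foot = -cfg.spring_k * (d - d0) * delta / d
        else:
            f_foot = np.zeros(2)
        if cfg.spring_damping > 0.0 and qdot is not None:
            qdot = np.asarray(qdot, float)
            v_f = leg.points["meta"].jac @ qdot[sl]
            v_p = ped_j[side] * qdot[CRANK_INDEX]
            f_foot = f_foot - cfg.spring_damping * (v_f - v_p)
        out[side] = (f_foot, -f_foot)
    return out


def pedal_force(cfg: ModelConfig, q, qdot=None) -> dict:
    """Reaction force applied to each pedal by its spring, N.

    Components are anterior-positive (x) and upward-positive (y)."""
    return {side: pair[1] for side, pair in spring_forces(cfg, q, qdot).items()}


# -- dynamics ------------------------------------------------------------------

_LEG_BODIES = (("thigh", "thigh_com"), ("shank", "shank_com"), ("foot", "foot_com"))


def _leg_mass_matrix(cfg: ModelConfig, leg: LegKin) -> np.ndarray:
    M = np.zeros((3, 3))
    for seg, com in _LEG_BODIES:
        p = cfg.segments[seg]
        J = leg.points[com].jac
        g = leg.ang_grad[seg]
        M += p.mass * (J.T @ J) + p.inertia_com * np.outer(g, g)
    return M


def mass_matrix(cfg: ModelConfig, q) -> np.ndarray:
    """7x7 generalized mass matrix; block-diagonal over legs and crank."""
    q = np.asarray(q, float)
    M = np.zeros((N_Q, N_Q))
    M[0:3, 0:3] = _leg_mass_matrix(cfg, leg_kinematics(cfg, q[0:3]))
    M[3:6, 3:6] = _leg_mass_matrix(cfg, leg_kinematics(cfg, q[3:6]))
    M[6, 6] = cfg.crank_inertia_eff
    return M


def _leg_bias_gravity(cfg: ModelConfig, leg: LegKin, gravity: float):
    """(Coriolis/centrifugal bias, gravity generalized force) for one leg."""
    bias = np.zeros(3)
    grav = np.zeros(3)
    gvec = np.array([0.0, -gravity])
    for seg, com in _LEG_BODIES:
        p = cfg.segments[seg]
        pk = leg.points[com]
        bias += p.mass * (pk.jac.T @ pk.jdot_qdot)
        grav += p.mass * (pk.jac.T @ gvec)
    return bias, grav


def forward_dynamics(cfg: ModelConfig, q, qdot, joint_torques=None,
                     resistive_torque: float = 0.0, include_springs: bool = True,
                     gravity_on: bool = True) -> np.ndarray:
    """Solve M(q) qddot = tau for the 7 generalized accelerations.

    ``joint_torques`` are the six muscle-generated joint torques
    (L hip/knee/ankle, R hip/knee/ankle); ``resistive_torque`` is the
    ergometer load torque magnitude opposing positive crank rotation.
    """
    q = np.asarray(q, float)
    qdot = np.asarray(qdot, float)
    M = np.zeros((N_Q, N_Q))
    rhs = np.zeros(N_Q)
    g = cfg.gravity if gravity_on else 0.0

    legs = {}
    for side, sl in (("L", slice(0, 3)), ("R", slice(3, 6))):
        leg = leg_kinematics(cfg, q[sl], qdot[sl])
        legs[side] = (leg, sl)
        M[sl, sl] = _leg_mass_matrix(cfg, leg)
        bias, grav = _leg_bias_gravity(cfg, leg, g)
        rhs[sl] += grav - bias
    M[6, 6] = cfg.crank_inertia_eff

    if joint_torques is not None:
        rhs[0:6] += np.asarray(joint_torques, float)

    if include_springs:
        ped = pedal_points(cfg, q[CRANK_INDEX])
        ped_j = pedal_point_jacobian(cfg, q[CRANK_INDEX])
        for side, (leg, sl) in legs.items():
            meta = leg.points["meta"]
            delta = meta.pos - ped[side]
            d0 = cfg.spring_rest_length
            if d0 == 0.0:
                f_foot = -cfg.spring_k * delta
            else:
                d = float(np.hypot(*delta))
                f_foot = (-cfg.spring_k * (d - d0) * delta / d
                          if d > 1e-12 else np.zeros(2))
            if cfg.spring_damping > 0.0:
                v_rel = meta.jac @ qdot[sl] - ped_j[side] * qdot[CRANK_INDEX]
                f_foot = f_foot - cfg.spring_damping * v_rel
            rhs[sl] += meta.jac.T @ f_foot
            # generalized force of the pedal reaction on the crank DOF
            rhs[CRANK_INDEX] += ped_j[side] @ (-f_foot)

    rhs[CRANK_INDEX] -= resistive_torque

    try:
        return np.linalg.solve(M, rhs)
    except np.linalg.LinAlgError as exc:   # pragma: no cover - valid configs are SPD
        raise ValueError("singular mass matrix") from exc


# -- energy audit helpers ------------------------------------------------------

def kinetic_energy(cfg: ModelConfig, q, qdot) -> float:
    qdot = np.asarray(qdot, float)
    return 0.5 * float(qdot @ mass_matrix(cfg, q) @ qdot)


def potential_energy(cfg: ModelConfig, q, gravity_on: bool = True) -> float:
    if not gravity_on:
        return 0.0
    q = np.asarray(q, float)
    e = 0.0
    for side, sl in (("L", slice(0, 3)), ("R", slice(3, 6))):
        leg = leg_kinematics(cfg, q[sl])
        for seg, com in _LEG_BODIES:
            e += cfg.segments[seg].mass * cfg.gravity * leg.points[com].pos[1]
    return e


def spring_energy(cfg: ModelConfig, q) -> float:
    q = np.asarray(q, float)
    ped = pedal_points(cfg, q[CRANK_INDEX])
    e = 0.0
    for side, sl in (("L", slice(0, 3)), ("R", slice(3, 6))):
        leg = leg_kinematics(cfg, q[sl])
        d = float(np.hypot(*(leg.points["meta"].pos - ped[side])))
        e += 0.5 * cfg.spring_k * (d - cfg.spring_rest_length) ** 2
    return e


def crank_torque_from_springs(cfg: ModelConfig, q, qdot=None) -> float:
    """Net torque of both pedal (spring) forces about the crank axis, N m.

    This is the quantity an instrumented crank measures as crank torque
    (the generalized force conjugate to the crank angle).
    """
    q = np.asarray(q, float)
    forces = pedal_force(cfg, q, qdot)
    ped_j = pedal_point_jacobian(cfg, q[CRANK_INDEX])
    tau = 0.0
    for side in ("L", "R"):
        tau += float(ped_j[side] @ forces[side])
    return tau


# -- inverse kinematics --------------------------------------------------------

def leg_ik(cfg: ModelConfig, meta_target, foot_angle: float):
    """Joint angles [hip, knee, ankle] placing the metatarsal point at
    ``meta_target`` with the foot axis at absolute angle ``foot_angle``
    (radians from +x).  Knee-forward solution.

    Raises ``ValueError`` when the target is out of reach.
    """
    meta_target = np.asarray(meta_target, float)
    ankle = meta_target - cfg.meta_from_ankle * _w(foot_angle)
    H = cfg.hip_position
    Lt = cfg.segments["thigh"].length
    Ls = cfg.segments["shank"].length
    d = ankle - H
    D = float(np.hypot(*d))
    if D > Lt + Ls or D < abs(Lt - Ls) or D < 1e-9:
        raise ValueError(f"ankle target out of reach (D={D:.3f} m)")
    cos_gamma = (Lt ** 2 + Ls ** 2 - D ** 2) / (2 * Lt * Ls)
    gamma = math.acos(min(1.0, max(-1.0, cos_gamma)))
    knee = math.pi - gamma
    # absolute angle of hip->ankle measured like phi (from downward vertical)
    beta = math.atan2(d[0], -d[1])
    cos_delta = (Lt ** 2 + D ** 2 - Ls ** 2) / (2 * Lt * D)
    delta = math.acos(min(1.0, max(-1.0, cos_delta)))
    hip = beta + delta          # knee-forward branch
    phi_s = hip - knee
    ankle_q = foot_angle - phi_s
    return np.array([hip, knee, ankle_q])
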