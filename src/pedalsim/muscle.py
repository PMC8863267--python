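"""Three-component Hill-type muscle-tendon unit (MTU) model.

Each MTU is a contractile component (CC) in series with a series elastic
component (SEC), with a parallel elastic component (PEC) across the CC.
Force-producing potential of the CC follows a force-velocity-length
relation; the SEC and PEC have quadratic-toe force-extension curves (C1 at
slack).  Contraction dynamics are the equilibrium form: the SEC force must
equal the CC plus PEC force at every instant, which is solved for the CC
velocity by inverting the force-velocity relation.

Curve shapes:

* active force-length: Gaussian ``exp(-((l/lopt - 1)/w)^2)`` with width
  ``w = fl_width`` (default 0.25), effectively zero outside the
  [0.4, 1.6] * lcc_opt operating band;
* force-velocity: Hill hyperbola for shortening, ``(1 + v)/(1 - v/a)`` with
  ``a = fv_shape`` and v normalized by vmax (shortening negative); a
  saturating eccentric branch that is C1 at v = 0 and tends to
  ``ecc_plateau``;
* SEC: ``fmax * (strain/strain_ref)^2`` above slack, strain_ref 4%;
* PEC: ``fmax * ((lnorm - 1)/pec_norm_width)^2`` above optimal length.

Excitation-to-activation dynamics are first order with separate activation
and deactivation time constants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import LEG_JOINTS, ModelConfig, MTUParams

__all__ = [
    "activation_rate", "fl_active", "fv", "fv_inverse", "sec_force",
    "pec_force", "contraction_rate", "equilibrium_lcc", "mtu_geometry",
    "mtu_forces", "mtu_joint_torques",
]

_ACT_FLOOR = 1e-3   # effective-activation floor in the fv inversion
_FL_FLOOR = 1e-3


def activation_rate(a, u, act_tau: float, deact_tau: float):
    """First-order excitation-to-activation dynamics, da/dt in 1/s.

    Uses the activation time constant when excitation exceeds activation
    and the (slower) deactivation constant otherwise.
    """
    a = np.asarray(a, float)
    u = np.asarray(u, float)
    tau = np.where(u >= a, act_tau, deact_tau)
    return (u - a) / tau


def fl_active(lcc_norm, width: float = 0.25):
    """Active force-length scale factor, Gaussian with peak 1 at lcc_norm=1."""
    lcc_norm = np.asarray(lcc_norm, float)
    return np.exp(-(((lcc_norm - 1.0) / width) ** 2))


def _ecc_c(params_shape: float, plateau: float) -> float:
    # C1 continuity of the eccentric branch with the Hill hyperbola at v=0
    return (plateau - 1.0) * params_shape / (params_shape + 1.0)


def fv(v_norm, shape: float = 0.25, plateau: float = 1.45):
    """Force-velocity scale factor; v_norm = v_cc / vmax, shortening negative.

    Hill hyperbola on the shortening side (fv(-1)=0, fv(0)=1), saturating
    eccentric branch tending to ``plateau``; C1 and monotone increasing.
    """
    v = np.asarray(v_norm, float)
    c = _ecc_c(shape, plateau)
    short = (1.0 + v) / (1.0 - v / shape)
    ecc = (plateau * v + c) / (v + c)
    out = np.where(v < 0.0, short, ecc)
    return np.where(v <= -1.0, 0.0, out)


def fv_inverse(scale, shape: float = 0.25, plateau: float = 1.45):
    """Normalized CC velocity at which fv equals ``scale`` (exact inverse)."""
    s = np.asarray(scale, float)
    c = _ecc_c(shape, plateau)
    v_short = shape * (s - 1.0) / (shape + s)
    with np.errstate(divide="ignore", invalid="ignore"):
        v_ecc = c * (s - 1.0) / (plateau - s)
    return np.where(s <= 1.0, v_short, v_ecc)


def sec_force(stretch, params: MTUParams):
    """Series-elastic force, N; quadratic toe, zero at/below slack (C1)."""
    stretch = np.asarray(stretch, float)
    ref = params.sec_strain_ref * max(params.l_slack_sec, 1e-9)
    return np.where(stretch > 0.0, params.fmax * (stretch / ref) ** 2, 0.0)


def pec_force(lcc, params: MTUParams):
    """Parallel-elastic force, N; engages beyond the optimal CC length."""
    lnorm = np.asarray(lcc, float) / params.lcc_opt
    x = (lnorm - 1.0) / params.pec_norm_width
    return np.where(lnorm > 1.0, params.fmax * x ** 2, 0.0)


@dataclass
class ContractionDiagnostics:
    """Flags raised while solving the CC velocity from force equilibrium."""

    clamped_shortening: bool = False
    clamped_lengthening: bool = False


def contraction_rate(a: float, lcc: float, l_mtu: float, params: MTUParams,
                     v_ecc_cap: float = 1.0, diagnostics: ContractionDiagnostics | None = None) -> float:
    """CC velocity dlcc/dt (m/s) from the equilibrium contraction dynamics.

    Enforces F_SEC(l_mtu - lcc) = a * fmax * fl(lcc) * fv(v) + F_PEC(lcc) by
    inverting the force-velocity curve for v.  When the required fv scale is
    outside the attainable range (below 0 or at/above the eccentric
    plateau), v is clamped to the maximal shortening / ``v_ecc_cap``
    lengthening velocity and flagged in ``diagnostics``.
    """
    f_sec = float(sec_force(l_mtu - lcc - params.l_slack_sec, params))
    f_pec = float(pec_force(lcc, params))
    a_eff = max(float(a), _ACT_FLOOR)
    fl = max(float(fl_active(lcc / params.lcc_opt, params.fl_width)), _FL_FLOOR)
    denom = a_eff * params.fmax * fl
    scale = (f_sec - f_pec) / denom
    if scale <= 0.0:
        v = -1.0
        if diagnostics is not None:
            diagnostics.clamped_shortening = True
    elif scale >= params.ecc_plateau:
        v = v_ecc_cap
        if diagnostics is not None:
            diagnostics.clamped_lengthening = True
    else:
        v = float(fv_inverse(scale, params.fv_shape, params.ecc_plateau))
        if v < -1.0:
            v = -1.0
            if diagnostics is not None:
                diagnostics.clamped_shortening = True
        elif v > v_ecc_cap:
            v = v_ecc_cap
            if diagnostics is not None:
                diagnostics.clamped_lengthening = True
    return v * params.vmax * params.lcc_opt


def equilibrium_lcc(a: float, l_mtu: float, params: MTUParams) -> float:
    """CC length at which the MTU is in isometric equilibrium (v = 0).

    Solves F_SEC(l_mtu - lcc) = a fmax fl(lcc) + F_PEC(lcc) by bisection;
    the left side decreases and the right side (weakly) increases with lcc
    beyond the optimum, so the root in the operating band is unique when
    the SEC engages.  Falls back to the taut-SEC length when it does not.
    """
    from scipy.optimize import brentq

    lo = 0.4 * params.lcc_opt
    hi = min(1.6 * params.lcc_opt, max(l_mtu - params.l_slack_sec, lo + 1e-9))

    def resid(lcc):
        return (float(sec_force(l_mtu - lcc - params.l_slack_sec, params))
                - a * params.fmax * float(fl_active(lcc / params.lcc_opt, params.fl_width))
                - float(pec_force(lcc, params)))

    rlo, rhi = resid(lo), resid(hi)
    if rlo * rhi > 0:
        # SEC slack across the whole band (or fully taut): return the
        # kinematically consistent CC length, clipped to the band
        return float(np.clip(l_mtu - params.l_slack_sec, lo, 1.6 * params.lcc_opt))
    return float(brentq(resid, lo, hi, xtol=1e-12))


# -- musculoskeletal geometry --------------------------------------------------

def _joint_angle(q, joint: str, side: str) -> float:
    base = 0 if side == "L" else 3
    return float(q[base + LEG_JOINTS.index(joint)])


def mtu_geometry(cfg: ModelConfig, q):
    """MTU lengths (m) and per-joint moment arms (m) at posture ``q``.

    Returns ``(lengths, arms)``: lengths is an (18,) array ordered like
    ``cfg.mtus``; arms is a list of dicts {joint_name: r} per MTU.  Moment
    arms satisfy r = -dl/dtheta by construction (lengths are integrals of
    the moment-arm polynomials from the reference posture).
    """
    q = np.asarray(q, float)
    P = np.polynomial.polynomial
    lengths = np.empty(len(cfg.mtus))
    arms = []
    for i, m in enumerate(cfg.mtus):
        l = m.l_ref
        r = {}
        for joint, coeffs in m.arms.items():
            c = np.asarray(coeffs, float)
            theta = _joint_angle(q, joint, m.side)
            theta0 = float(m.q_ref.get(joint, 0.0))
            anti = P.polyint(c)
            l -= float(P.polyval(theta, anti) - P.polyval(theta0, anti))
            r[joint] = float(P.polyval(theta, c))
        lengths[i] = l
        arms.append(r)
    return lengths, arms


def mtu_forces(cfg: ModelConfig, q, lcc) -> np.ndarray:
    """Tendon (SEC) force of every MTU, N — the force applied to the skeleton."""
    lengths, _ = mtu_geometry(cfg, q)
    lcc = np.asarray(lcc, float)
    out = np.empty(len(cfg.mtus))
    for i, m in enumerate(cfg.mtus):
        out[i] = float(sec_force(lengths[i] - lcc[i] - m.l_slack_sec, m))
    return out


def mtu_joint_torques(cfg: ModelConfig, q, lcc) -> np.ndarray:
    """Six joint torques (L hip/knee/ankle, R hip/knee/ankle), N m.

    tau_joint = sum over MTUs of tendon force times the signed moment arm.
    """
    q = np.asarray(q, float)
    forces = mtu_forces(cfg, q, lcc)
    _, arms = mtu_geometry(cfg, q)
    tau = np.zeros(6)
    for i, m in enumerate(cfg.mtus):
        base = 0 if m.side == "L" else 3
        for joint, r in arms[i].items():
            tau[base + LEG_JOINTS.index(joint)] += forces[i] * r
    return tau
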