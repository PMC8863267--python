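"""Synthetic-data generation: forward simulation and tracking targets.

This module stands in for the experimental dataset.  It forward-simulates
the bicycle-rider model over whole crank cycles and converts one steady
cycle into a tracking target (pedal angle and pedal-force means with SD
bands) that the collocation problem can track.

Cadence regulation.  A rider on an ergometer holds a target cadence; the
generator emulates this with a servo torque on the crank degree of freedom
driving it toward constant cadence.  The servo torque is *not* part of the
collocation model, so after simulation the generator measures the crank
torque delivered through the pedals and re-estimates the resistive-torque
profile from the crank angular-momentum balance (T_res = T_crank -
I_eff * alpha).  The estimated profile absorbs the servo torque, making the
generated cycle dynamically near-consistent with the collocation model
that uses it — the same identification step applied to the experimental
ergometer.

Two generators are provided: a muscle-driven one controlled by phasic
excitation patterns keyed to crank angle, and a torque-actuated one in
which the legs follow the pedals via a computed-torque (PD) law.  The
latter is exactly consistent on the leg side because the applied joint
torques are recorded as the controls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from . import muscle, rigidbody
from .config import CRANK_INDEX, MTU_NAMES, N_MUS, N_Q, ModelConfig
from .crankload import CrankData, ResistiveTorqueProfile, estimate_resistive_torque
from .models import MuscleModel, TorqueModel, tracked_outputs
from .transcription import TrackingTarget, Trajectory

__all__ = [
    "ExcitationPattern", "default_patterns", "forward_simulate",
    "CycleResult", "generate_reference_cycle", "generate_target",
    "sd_bands", "pattern_excitations",
]


# -- excitation patterns -------------------------------------------------------

@dataclass
class ExcitationPattern:
    """Phasic excitation burst for one MTU, keyed to crank angle.

    The burst is a smooth trapezoid between ``onset_deg`` and
    ``offset_deg`` (circular window; offset may be numerically smaller
    than onset for bursts spanning top dead center) with cosine ramps of
    width ``ramp_deg`` and a resting baseline.
    """

    muscle: str                 # e.g. "VAS_L"
    onset_deg: float
    offset_deg: float
    amplitude: float = 0.5
    ramp_deg: float = 30.0
    baseline: float = 0.02

    def __post_init__(self) -> None:
        if not 0.0 <= self.amplitude <= 1.0:
            raise ValueError("amplitude must lie in [0, 1]")

    def value(self, crank_deg) -> np.ndarray:
        theta = np.mod(np.asarray(crank_deg, float), 360.0)
        span = np.mod(self.offset_deg - self.onset_deg, 360.0)
        pos = np.mod(theta - self.onset_deg, 360.0)
        r = self.ramp_deg
        env = np.zeros_like(pos)
        inside = pos <= span
        ramp_in = inside & (pos < r)
        ramp_out = inside & (span - pos < r)
        flat = inside & ~ramp_in & ~ramp_out
        env[flat] = 1.0
        env[ramp_in] = 0.5 * (1 - np.cos(np.pi * pos[ramp_in] / r))
        env[ramp_out] = 0.5 * (1 - np.cos(np.pi * (span - pos[ramp_out]) / r))
        out = self.baseline + (self.amplitude - self.baseline) * env
        return out if out.ndim else float(out)


# burst windows (degrees of crank angle, left leg; 0 = left pedal at top,
# downstroke 0-180) in the style of pedaling EMG: extensors fire on the
# downstroke, flexors and TA on the upstroke
_PATTERN_WINDOWS = {
    "GMAX": (350.0, 130.0, 0.45),
    "VAS": (330.0, 120.0, 0.40),
    "RF": (290.0, 80.0, 0.30),
    "HAM": (40.0, 200.0, 0.35),
    "BFsh": (90.0, 230.0, 0.25),
    "GAS": (50.0, 220.0, 0.35),
    "SOL": (20.0, 170.0, 0.40),
    "TA": (250.0, 360.0, 0.30),
    "IP": (160.0, 300.0, 0.35),
}


def default_patterns(cfg: ModelConfig) -> list[ExcitationPattern]:
    """Phasic burst library for all 18 MTUs; the right leg lags 180 deg."""
    pats = []
    for m in cfg.mtus:
        on, off, amp = _PATTERN_WINDOWS[m.name]
        shift = 0.0 if m.side == "L" else 180.0
        pats.append(ExcitationPattern(m.label, math.fmod(on + shift, 360.0),
                                      math.fmod(off + shift, 360.0), amp))
    return pats


def pattern_excitations(cfg: ModelConfig, patterns, crank_angle_rad: float) -> np.ndarray:
    """Excitation vector (18,) at a crank angle, ordered like cfg.mtus."""
    by_label = {p.muscle: p for p in patterns}
    theta = math.degrees(crank_angle_rad)
    return np.array([by_label[m.label].value(theta) for m in cfg.mtus])


# -- forward simulation --------------------------------------------------------

def forward_simulate(model, controls, x0, t_span, method: str = "Radau",
                     rtol: float = 1e-6, atol: float = 1e-8,
                     crank_torque_extra=None, max_step: float = np.inf):
    """Integrate the model ODEs with a stiff-capable adaptive integrator.

    ``controls(t, x)`` returns the control vector (open or closed loop);
    ``crank_torque_extra(t, x)``, if given, adds a torque on the crank DOF
    (exact, since the crank row of the mass matrix is decoupled).  Returns
    the scipy ``OdeResult`` with dense output enabled.

    The default method is implicit (Radau) because the 1e5 N/m foot-pedal
    springs make the system stiff; explicit high-order methods remain
    available for cross-checks.
    """
    i_eff = model.cfg.crank_inertia_eff
    rate_idx = model.crank_rate_index

    def rhs(t, x):
        xdot = np.asarray(model.f(x, controls(t, x)), float)
        if crank_torque_extra is not None:
            xdot[rate_idx] += crank_torque_extra(t, x) / i_eff
        return xdot

    sol = solve_ivp(rhs, t_span, np.asarray(x0, float), method=method,
                    rtol=rtol, atol=atol, dense_output=True, max_step=max_step)
    if not sol.success:
        raise RuntimeError(f"integration failed at t={sol.t[-1]:.4f}: {sol.message}")
    return sol


# -- reference-cycle generation ------------------------------------------------

def _foot_angle_schedule(crank_angle: float, chi0: float = -0.20,
                         amp: float = 0.20, phase: float = 0.6) -> float:
    """Nominal foot-axis angle (rad from +x) as a function of crank angle."""
    return chi0 + amp * math.sin(crank_angle + phase)


def leg_reference(cfg: ModelConfig, crank_angle: float) -> np.ndarray:
    """Desired six leg joint angles tracking the pedals at ``crank_angle``."""
    ped = rigidbody.pedal_points(cfg, crank_angle)
    qL = rigidbody.leg_ik(cfg, ped["L"], _foot_angle_schedule(crank_angle))
    qR = rigidbody.leg_ik(cfg, ped["R"], _foot_angle_schedule(crank_angle + math.pi))
    return np.concatenate([qL, qR])


def _leg_reference_rate(cfg: ModelConfig, crank_angle: float, omega: float,
                        h: float = 1e-5) -> np.ndarray:
    dq = (leg_reference(cfg, crank_angle + h) - leg_reference(cfg, crank_angle - h)) / (2 * h)
    return dq * omega


@dataclass
class CycleResult:
    """One steady generated crank cycle plus its identified crank load."""

    trajectory: Trajectory                  # n-node cycle, crank 0 -> 2*pi
    target: TrackingTarget
    profile: ResistiveTorqueProfile         # estimated resistive torque
    tFinal: float
    outputs: np.ndarray = field(repr=False, default=None)  # n x 6 noiseless


_PD_KP = np.array([800.0, 600.0, 200.0] * 2)
_PD_KD = np.array([60.0, 40.0, 10.0] * 2)
_SERVO_KP = 600.0
_SERVO_KD = 240.0


def _servo(cfg: ModelConfig, omega: float):
    def torque(t, x):
        theta_ref = omega * t
        return (_SERVO_KP * (theta_ref - x[CRANK_INDEX])
                + _SERVO_KD * (omega - x[N_Q + CRANK_INDEX]))
    return torque


def _extract_cycle(cfg, model, sol, controls, omega, n):
    """Resample the second simulated revolution onto n nodes and identify
    the resistive profile from the simulated crank torque."""
    # locate crank-angle crossings of 2*pi and 4*pi on the dense solution
    tg = np.linspace(sol.t[0], sol.t[-1], 4001)
    theta = sol.sol(tg)[CRANK_INDEX]
    t_start = float(np.interp(2 * math.pi, theta, tg))
    t_end = float(np.interp(4 * math.pi, theta, tg))
    t_final = t_end - t_start

    # crank-torque series over the final 1.5 cycles for the Eq-1 estimator
    ts = np.linspace(max(sol.t[0], t_start - 0.25 * t_final), t_end, 1200)
    xs = sol.sol(ts)
    torque = np.array([rigidbody.crank_torque_from_springs(cfg, x[:N_Q], x[N_Q:2 * N_Q])
                       for x in xs.T])
    profile = estimate_resistive_torque(
        CrankData(ts, xs[CRANK_INDEX], torque), cfg.crank_inertia_eff)

    tn = np.linspace(t_start, t_end, n)
    states = sol.sol(tn).T.copy()
    states[:, CRANK_INDEX] -= 2 * math.pi
    ctrl = np.array([controls(t, x) for t, x in zip(tn, states)])
    traj = Trajectory(t_final, states, ctrl)
    outputs = np.array([tracked_outputs(cfg, x[:N_Q]) for x in states])
    return traj, outputs, profile, t_final


def sd_bands(outputs: np.ndarray, frac: float = 0.05,
             floor_angle: float = 1.0, floor_force: float = 5.0) -> np.ndarray:
    """Inter-subject-style SD bands: a fraction of each variable's range
    with a floor (degrees for angles, N for forces)."""
    rng = outputs.max(axis=0) - outputs.min(axis=0)
    floors = np.array([floor_angle, floor_angle] + [floor_force] * 4)
    return np.maximum(frac * rng, floors) * np.ones_like(outputs)


def _symmetrize(outputs: np.ndarray) -> np.ndarray:
    """Replace right-leg columns by the left-leg data shifted half a cycle.

    Node n-1 repeats node 0 in phase, so the shift acts on the first n-1
    nodes; n-1 must be even for an exact half-cycle shift.
    """
    n = len(outputs)
    if (n - 1) % 2:
        raise ValueError("symmetry shift needs an even number of intervals")
    half = (n - 1) // 2
    out = outputs.copy()
    pairs = {1: 0, 4: 2, 5: 3}       # right column <- left column
    for rc, lc in pairs.items():
        core = outputs[:-1, lc]
        out[:-1, rc] = np.roll(core, -half)
        out[-1, rc] = out[0, rc]
    return out


def generate_reference_cycle(cfg: ModelConfig, n: int, cadence: float | None = None,
                             rtol: float = 1e-6, atol: float = 1e-8) -> CycleResult:
    """Torque-actuated reference cycle via a computed-torque (PD) rider.

    The legs track the pedal circle; the crank servo holds the cadence
    (default 2*pi/tFinal).  Applied joint torques are recorded as the
    controls, so the returned trajectory is dynamically consistent with a
    :class:`TorqueModel` built from the returned resistive profile.
    """
    omega = cadence if cadence is not None else 2 * math.pi / cfg.tFinal
    model = TorqueModel(cfg)

    def controls(t, x):
        th = x[CRANK_INDEX]
        q_des = leg_reference(cfg, th)
        qd_des = _leg_reference_rate(cfg, th, x[N_Q + CRANK_INDEX])
        return np.clip(_PD_KP * (q_des - x[:6]) + _PD_KD * (qd_des - x[N_Q:N_Q + 6]),
                       -cfg.torque_bound, cfg.torque_bound)

    q0 = np.concatenate([leg_reference(cfg, 0.0), [0.0]])
    qd0 = np.concatenate([_leg_reference_rate(cfg, 0.0, omega), [omega]])
    x0 = np.concatenate([q0, qd0])
    t_end = 2.35 * 2 * math.pi / omega
    sol = forward_simulate(model, controls, x0, (0.0, t_end), rtol=rtol, atol=atol,
                           crank_torque_extra=_servo(cfg, omega))
    traj, outputs, profile, t_final = _extract_cycle(cfg, model, sol, controls, omega, n)
    target = TrackingTarget(outputs, sd_bands(outputs))
    return CycleResult(traj, target, profile, t_final, outputs)


def generate_target(cfg: ModelConfig, patterns=None, n: int = 31,
                    sd_model: dict | None = None, seed: int | None = None,
                    noise_frac: float = 0.0, symmetry: bool = False,
                    cadence: float | None = None, rtol: float = 1e-5,
                    atol: float = 1e-7) -> CycleResult:
    """Muscle-driven synthetic tracking target.

    Forward-simulates the full 50-state model under the phasic excitation
    patterns (closed loop on crank angle) with cadence regulation, then
    samples pedal angle and forces of both legs at ``n`` nodes.  Optional
    seeded Gaussian noise (``noise_frac`` of each variable's range) is
    added to the means; ``symmetry`` replaces the right-leg columns by the
    left-leg data shifted 180 degrees of the cycle.
    """
    if patterns is None:
        patterns = default_patterns(cfg)
    omega = cadence if cadence is not None else 2 * math.pi / cfg.tFinal
    model = MuscleModel(cfg)

    def controls(t, x):
        return pattern_excitations(cfg, patterns, x[CRANK_INDEX])

    q0 = np.concatenate([leg_reference(cfg, 0.0), [0.0]])
    qd0 = np.concatenate([_leg_reference_rate(cfg, 0.0, omega), [omega]])
    a0 = pattern_excitations(cfg, patterns, 0.0)
    lengths, _ = muscle.mtu_geometry(cfg, q0)
    lcc0 = np.array([muscle.equilibrium_lcc(a0[i], lengths[i], m)
                     for i, m in enumerate(cfg.mtus)])
    x0 = np.concatenate([q0, qd0, a0, lcc0])
    t_end = 2.35 * 2 * math.pi / omega
    sol = forward_simulate(model, controls, x0, (0.0, t_end), rtol=rtol, atol=atol,
                           crank_torque_extra=_servo(cfg, omega))
    traj, outputs, profile, t_final = _extract_cycle(cfg, model, sol, controls, omega, n)

    means = outputs.copy()
    if symmetry:
        means = _symmetrize(means)
    sds_arr = sd_bands(means, **(sd_model or {}))
    means = apply_noise(means, noise_frac, seed)
    target = TrackingTarget(means, sds_arr)
    return CycleResult(traj, target, profile, t_final, outputs)


def apply_noise(means: np.ndarray, noise_frac: float, seed: int | None) -> np.ndarray:
    """Seeded Gaussian perturbation of the target means.

    Noise SD is ``noise_frac`` of each variable's range; ``noise_frac = 0``
    returns the means unchanged (the default for recovery studies)."""
    if noise_frac <= 0.0:
        return means
    rng = np.random.default_rng(seed)
    span = means.max(axis=0) - means.min(axis=0)
    return means + rng.normal(0.0, noise_frac, means.shape) * span
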