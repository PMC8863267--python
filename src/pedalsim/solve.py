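"""Solver orchestration: initial guesses, NLP solution, sensitivity sweeps.

The transcribed problem is solved with scipy's SQP solver (SLSQP) by
default, using the analytic objective gradient and the colored sparse
finite-difference constraint Jacobian from the transcription module
(densified for the solver).  ``method="trust-constr"`` keeps the Jacobian
sparse for larger problems.  A solve may claim success only if the largest
constraint violation is below the feasibility tolerance; reports always
carry the term-wise objective breakdown and the violation, even on
failure.  Everything here is deterministic: identical inputs produce
identical reports.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import NonlinearConstraint, minimize

from . import rigidbody, synth
from .config import CRANK_INDEX, N_MUS, N_Q, ModelConfig
from .models import MuscleModel, TorqueModel
from .muscle import equilibrium_lcc, mtu_geometry
from .transcription import (NLPProblem, ObjectiveWeights, TrackingTarget,
                            Trajectory, build_nlp)

__all__ = [
    "SolveReport", "SolverOptions", "static_initial_guess",
    "dynamic_initial_guess", "solve_tracking", "weight_sweep", "node_sweep",
]

DEFAULT_WEIGHT_PAIRS = ((1.0, 0.0), (0.0, 1.0), (1.0, 0.5), (1.0, 1.0),
                        (1.0, 5.0), (1.0, 10.0))
DEFAULT_NODE_LIST = (11, 31, 51, 91, 181)


@dataclass
class SolverOptions:
    """Options for :func:`solve_tracking`.

    When the initial guess violates the dynamics badly (max constraint
    residual above ``restoration_threshold``, e.g. the static guess, whose
    constant posture stretches the stiff pedal springs as the crank
    ramps), a feasibility-restoration stage first minimizes the squared
    constraint residuals with a trust-region least-squares pass before the
    SQP stage — the standard remedy for far-from-feasible starts of
    collocation problems.
    """

    method: str = "slsqp"
    max_iterations: int = 500
    ftol: float = 1e-8
    feasibility_tol: float = 1e-6
    restoration_threshold: float = 1.0
    restoration_max_nfev: int = 250


@dataclass
class SolveReport:
    """Outcome of one tracking solve, term-wise."""

    status: str
    success: bool
    iterations: int
    objective: float
    tracking_term: float
    activation_term: float
    max_violation: float
    wall_time_s: float
    n: int = 0
    weights: tuple = (1.0, 1.0)
    message: str = ""

    def as_dict(self) -> dict:
        return {
            "status": self.status, "success": self.success,
            "iterations": self.iterations, "objective": self.objective,
            "tracking_term": self.tracking_term,
            "activation_term": self.activation_term,
            "max_violation": self.max_violation,
            "wall_time_s": self.wall_time_s, "n": self.n,
            "weights": list(self.weights), "message": self.message,
        }


# -- initial guesses -----------------------------------------------------------

def _base_state(model, crank_angle: float, crank_rate: float) -> np.ndarray:
    """State with the legs posed on the pedals at the given crank angle."""
    cfg = model.cfg
    q = np.concatenate([synth.leg_reference(cfg, crank_angle), [crank_angle]])
    qdot = np.zeros(N_Q)
    qdot[CRANK_INDEX] = crank_rate
    if isinstance(model, MuscleModel):
        act = np.full(N_MUS, 0.1)
        lengths, _ = mtu_geometry(cfg, q)
        lcc = np.array([equilibrium_lcc(act[i], lengths[i], m)
                        for i, m in enumerate(cfg.mtus)])
        return np.concatenate([q, qdot, act, lcc])
    return np.concatenate([q, qdot])


def static_initial_guess(model, n: int, tFinal: float | None = None) -> Trajectory:
    """Constant states and controls at every node, except the crank angle.

    The crank angle ramps linearly from 0 to 2*pi (a literally constant
    crank angle cannot satisfy both pinned end values) and the crank rate
    is the constant cycle-average; every other coordinate is identical
    across nodes.  Activations start at 0.1, excitations/torques at their
    neutral values.
    """
    cfg = model.cfg
    tFinal = tFinal if tFinal is not None else cfg.tFinal
    x = _base_state(model, 0.0, 2 * math.pi / tFinal)
    states = np.tile(x, (n, 1))
    states[:, CRANK_INDEX] = np.linspace(0.0, 2 * math.pi, n)
    if isinstance(model, MuscleModel):
        controls = np.full((n, model.nu), 0.1)
    else:
        controls = np.zeros((n, model.nu))
    return Trajectory(tFinal, states, controls)


def dynamic_initial_guess(model, n: int, patterns=None,
                          rtol: float = 1e-6, atol: float = 1e-8) -> Trajectory:
    """Dynamically consistent guess from a forward simulation.

    For the muscle model the simulation is driven by the phasic excitation
    patterns; for the torque model by the computed-torque rider.  The
    sampled cycle satisfies the defect constraints to the combination of
    integrator tolerance and the O(dt) backward-Euler discretization error.
    """
    cfg = model.cfg
    if isinstance(model, MuscleModel):
        res = synth.generate_target(cfg, patterns=patterns, n=n, rtol=rtol, atol=atol)
    else:
        res = synth.generate_reference_cycle(cfg, n, rtol=rtol, atol=atol)
    return res.trajectory


# -- solving -------------------------------------------------------------------

def solve_tracking(problem: NLPProblem, guess: Trajectory,
                   options: SolverOptions | None = None) -> tuple[Trajectory, SolveReport]:
    """Solve the transcribed tracking NLP from the given initial guess."""
    opts = options or SolverOptions()
    z0 = guess.pack()
    if z0.size != problem.n_decision:
        raise ValueError(f"guess dimension {z0.size} != problem dimension "
                         f"{problem.n_decision}")
    lo, hi = problem.decision_bounds()
    z0 = np.clip(z0, lo, hi)
    t0 = time.perf_counter()

    if (opts.restoration_max_nfev > 0 and problem.n_constraints
            and float(np.max(np.abs(problem.constraints(z0)))) > opts.restoration_threshold):
        from scipy.optimize import least_squares
        ls = least_squares(problem.constraints, z0, jac=problem.jacobian,
                           bounds=(lo, hi), method="trf", xtol=1e-14,
                           ftol=1e-14, gtol=1e-14,
                           max_nfev=opts.restoration_max_nfev)
        z0 = np.asarray(ls.x, float)

    if opts.method == "slsqp":
        res = minimize(
            problem.objective, z0, jac=problem.gradient,
            bounds=list(zip(lo, hi)),
            constraints=[{"type": "eq", "fun": problem.constraints,
                          "jac": lambda z: problem.jacobian(z).toarray()}],
            method="SLSQP",
            options={"maxiter": opts.max_iterations, "ftol": opts.ftol},
        )
        iterations = int(res.get("nit", -1))
    elif opts.method == "trust-constr":
        con = NonlinearConstraint(problem.constraints, 0.0, 0.0,
                                  jac=problem.jacobian)
        res = minimize(
            problem.objective, z0, jac=problem.gradient,
            bounds=list(zip(lo, hi)), constraints=[con], method="trust-constr",
            options={"maxiter": opts.max_iterations, "gtol": 1e-8,
                     "xtol": 1e-10},
        )
        iterations = int(res.get("niter", -1))
    else:
        raise ValueError(f"unknown method {opts.method!r}")

    wall = time.perf_counter() - t0
    z = np.asarray(res.x, float)
    traj = problem.unpack(z)
    viol = float(np.max(np.abs(problem.constraints(z)))) if problem.n_constraints else 0.0
    j, jt, ja = problem.objective_terms(z)
    success = bool(res.success) and viol <= opts.feasibility_tol
    report = SolveReport(
        status="converged" if success else "failed",
        success=success, iterations=iterations, objective=j,
        tracking_term=jt, activation_term=ja, max_violation=viol,
        wall_time_s=wall, n=problem.n,
        weights=(problem.weights.w1, problem.weights.w2),
        message=str(res.get("message", "")),
    )
    return traj, report


# -- sensitivity harnesses -----------------------------------------------------

def weight_sweep(model, target: TrackingTarget, n: int,
                 weight_pairs=DEFAULT_WEIGHT_PAIRS, tFinal: float | None = None,
                 guess: Trajectory | None = None,
                 options: SolverOptions | None = None):
    """One tracking solve per (w1, w2) pair; returns list of
    (weights, Trajectory, SolveReport)."""
    tFinal = tFinal if tFinal is not None else model.cfg.tFinal
    if guess is None:
        guess = dynamic_initial_guess(model, n)
    rows = []
    for w1, w2 in weight_pairs:
        problem = build_nlp(model, target, ObjectiveWeights(w1, w2), n, tFinal)
        traj, report = solve_tracking(problem, guess, options)
        rows.append(((w1, w2), traj, report))
    return rows


def node_sweep(model, target: TrackingTarget, weights: ObjectiveWeights,
               node_list=DEFAULT_NODE_LIST, tFinal: float | None = None,
               options: SolverOptions | None = None, guess_kind: str = "dynamic"):
    """One tracking solve per node density; reports include wall time."""
    tFinal = tFinal if tFinal is not None else model.cfg.tFinal
    rows = []
    for n in node_list:
        if guess_kind == "dynamic":
            guess = dynamic_initial_guess(model, n)
        else:
            guess = static_initial_guess(model, n, tFinal)
        problem = build_nlp(model, target, weights, n, tFinal)
        traj, report = solve_tracking(problem, guess, options)
        rows.append((n, traj, report))
    return rows
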