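"""Shared fixtures: model configs and (expensive) solved problems.

The solved-problem fixtures are session-scoped because each tracking solve
takes tens of seconds; acceptance and behavioural tests share them.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from pedalsim import config as pcfg
from pedalsim import solve as psolve
from pedalsim import synth
from pedalsim.models import TorqueModel
from pedalsim.transcription import ObjectiveWeights, Trajectory, build_nlp

settings.register_profile("ci", deadline=None, max_examples=25, derandomize=True)
settings.load_profile("ci")


def subsample_trajectory(traj: Trajectory, n: int) -> Trajectory:
    """Exact node subsampling (source interval count must divide evenly)."""
    stride, rem = divmod(traj.n - 1, n - 1)
    assert rem == 0, "node counts incompatible for exact subsampling"
    idx = np.arange(0, traj.n, stride)
    return Trajectory(traj.tFinal, traj.states[idx], traj.controls[idx])


@pytest.fixture(scope="session")
def cfg():
    return pcfg.default_config()


@pytest.fixture(scope="session")
def ref61(cfg):
    """Dense torque-actuated reference cycle; the fixed synthetic problem."""
    return synth.generate_reference_cycle(cfg, 61)


@pytest.fixture(scope="session")
def torque_model(cfg, ref61):
    return TorqueModel(cfg, ref61.profile)


@pytest.fixture(scope="session")
def sweep11(torque_model, ref61):
    """Weight sweep over the six (w1, w2) pairs at n = 11."""
    guess = subsample_trajectory(ref61.trajectory, 11)
    return psolve.weight_sweep(torque_model, ref61.target, 11,
                               psolve.DEFAULT_WEIGHT_PAIRS,
                               tFinal=ref61.tFinal, guess=guess)


@pytest.fixture(scope="session")
def solve31(torque_model, ref61):
    """Equal-weights solve at n = 31 on the same synthetic problem."""
    guess = subsample_trajectory(ref61.trajectory, 31)
    problem = build_nlp(torque_model, ref61.target, ObjectiveWeights(1.0, 1.0),
                        31, ref61.tFinal)
    # larger problem: stop once the objective is resolved to ~0.3% of its
    # magnitude instead of polishing for hundreds more SQP iterations
    return psolve.solve_tracking(problem, guess,
                                 psolve.SolverOptions(ftol=1e-7))


@pytest.fixture(scope="session")
def static11(torque_model, ref61):
    """Equal-weights solve at n = 11 from the static initial guess."""
    guess = psolve.static_initial_guess(torque_model, 11, ref61.tFinal)
    problem = build_nlp(torque_model, ref61.target, ObjectiveWeights(1.0, 1.0),
                        11, ref61.tFinal)
    return psolve.solve_tracking(problem, guess)


@pytest.fixture(scope="session")
def muscle_cycle(cfg):
    """One muscle-driven synthetic cycle (moderate integrator tolerance)."""
    return synth.generate_target(cfg, n=21, symmetry=True, seed=7,
                                 rtol=1e-4, atol=1e-6)
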