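"""Direct-collocation transcription of the periodic tracking problem.

The continuous optimal-control problem (track pedal angles/forces over one
crank cycle while penalizing cubed muscle activation) is discretized at
``n`` equally spaced nodes with backward-Euler defect constraints::

    (x_{i+1} - x_i)/dt - f(x_{i+1}, u_{i+1}) = 0,   i = 1..n-1

plus periodicity of all states and controls between the first and last node
except the crank angle, which is pinned to 0 at the first node and 2*pi at
the last.  For the full 50-state, 18-control model this gives 68n decision
variables and 50(n-1) + 69 equality constraints.

The objective is

    J = W1 * mean over (v x n) of ((Yhat - Y)/SD)^2
      + W2 * sum_m sum_i a_mi^3 / (nMus * n)

with both terms reported separately.  The constraint Jacobian is evaluated
by forward finite differences grouped by a greedy structural coloring of
the manually constructed sparsity pattern, so the number of constraint
evaluations per Jacobian is O(nx + nu), independent of n.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .models import N_OUTPUTS, OUTPUT_NAMES

__all__ = [
    "Trajectory", "TrackingTarget", "ObjectiveWeights", "NLPProblem",
    "objective", "defect_constraints", "boundary_constraints", "build_nlp",
    "jacobian_sparsity", "color_columns", "fd_jacobian",
]


@dataclass
class Trajectory:
    """States and controls at n equally spaced nodes over one crank cycle."""

    tFinal: float
    states: np.ndarray    # n x nx
    controls: np.ndarray  # n x nu

    def __post_init__(self) -> None:
        self.states = np.atleast_2d(np.asarray(self.states, float))
        self.controls = np.atleast_2d(np.asarray(self.controls, float))
        if len(self.states) != len(self.controls):
            raise ValueError("states and controls must share the node count")

    @property
    def n(self) -> int:
        return len(self.states)

    @property
    def dt(self) -> float:
        return self.tFinal / (self.n - 1)

    @property
    def times(self) -> np.ndarray:
        return np.linspace(0.0, self.tFinal, self.n)

    def pack(self) -> np.ndarray:
        """Node-major decision vector [x_1, u_1, ..., x_n, u_n]."""
        return np.hstack([self.states, self.controls]).ravel()

    @classmethod
    def unpack(cls, z, n: int, nx: int, nu: int, tFinal: float) -> "Trajectory":
        blocks = np.asarray(z, float).reshape(n, nx + nu)
        return cls(tFinal, blocks[:, :nx], blocks[:, nx:])


@dataclass
class TrackingTarget:
    """Per-node means and SDs of the 6 tracked pedal variables."""

    means: np.ndarray               # n x 6
    sds: np.ndarray                 # n x 6
    names: tuple = OUTPUT_NAMES

    def __post_init__(self) -> None:
        self.means = np.atleast_2d(np.asarray(self.means, float))
        self.sds = np.atleast_2d(np.asarray(self.sds, float))
        if self.means.shape != self.sds.shape:
            raise ValueError("means and sds shapes differ")
        if np.any(self.sds <= 0):
            raise ValueError("SDs must be strictly positive")

    @property
    def n(self) -> int:
        return len(self.means)

    def resample(self, n: int) -> "TrackingTarget":
        """Periodic linear resampling onto ``n`` nodes spanning one cycle.

        Node phases are i/(n-1) of the cycle with the last node equal in
        phase to the first (crank at 360 vs 0 degrees).
        """
        if n == self.n:
            return self
        src = np.linspace(0.0, 1.0, self.n)
        dst = np.linspace(0.0, 1.0, n)
        means = np.column_stack([np.interp(dst, src, self.means[:, k])
                                 for k in range(self.means.shape[1])])
        sds = np.column_stack([np.interp(dst, src, self.sds[:, k])
                               for k in range(self.sds.shape[1])])
        return TrackingTarget(means, sds, self.names)


@dataclass
class ObjectiveWeights:
    """Weights of the tracking (w1) and activation/effort (w2) terms."""

    w1: float = 1.0
    w2: float = 1.0

    def __post_init__(self) -> None:
        if self.w1 < 0 or self.w2 < 0 or (self.w1 == 0 and self.w2 == 0):
            raise ValueError("weights must be >= 0 and not both zero")


# -- objective ----------------------------------------------------------------

def tracking_term(outputs: np.ndarray, target: TrackingTarget) -> float:
    """Mean squared SD-normalized tracking error over (v x n)."""
    if np.any(target.sds <= 0):
        raise ValueError("SDs must be strictly positive")
    resid = (outputs - target.means) / target.sds
    return float(np.sum(resid ** 2)) / resid.size


def objective(traj: Trajectory, target: TrackingTarget, weights: ObjectiveWeights,
              model) -> tuple[float, float, float]:
    """(J, tracking term, activation term) for a trajectory."""
    outputs = np.array([model.outputs(x) for x in traj.states])
    jt = tracking_term(outputs, target)
    ja = _effort_term(traj, model)
    return weights.w1 * jt + weights.w2 * ja, jt, ja


def _effort_term(traj: Trajectory, model) -> float:
    from .models import MuscleModel
    n = traj.n
    if isinstance(model, MuscleModel):
        from .config import N_MUS, N_Q
        act = traj.states[:, 2 * N_Q:2 * N_Q + N_MUS]
        return float(np.sum(act ** 3)) / (N_MUS * n)
    tot = sum(model.effort(u) for u in traj.controls)
    return tot / (model.nu * n)


# -- constraints --------------------------------------------------------------

def defect_constraints(traj: Trajectory, dynamics) -> np.ndarray:
    """Backward-Euler defects, nx*(n-1) residuals (rad/s, rad/s^2, ... units)."""
    dt = traj.dt
    res = []
    for i in range(traj.n - 1):
        f = np.asarray(dynamics(traj.states[i + 1], traj.controls[i + 1]), float)
        if not np.all(np.isfinite(f)):
            raise FloatingPointError(f"non-finite dynamics output at node {i + 1}")
        res.append((traj.states[i + 1] - traj.states[i]) / dt - f)
    return np.concatenate(res) if res else np.empty(0)


def boundary_constraints(traj: Trajectory, crank_index: int = 6) -> np.ndarray:
    """Periodicity and crank pinning residuals: (nx-1) + nu + 2 rows.

    All states except the crank angle and all controls are periodic; the
    crank angle is 0 at the first node and 2*pi at the last.
    """
    x0, xn = traj.states[0], traj.states[-1]
    u0, un = traj.controls[0], traj.controls[-1]
    keep = np.arange(len(x0)) != crank_index
    return np.concatenate([
        x0[keep] - xn[keep],
        u0 - un,
        [x0[crank_index] - 0.0],
        [xn[crank_index] - 2.0 * math.pi],
    ])


# -- sparsity & coloring ------------------------------------------------------

def jacobian_sparsity(n: int, nx: int, nu: int, crank_index: int) -> sp.csc_matrix:
    """Boolean sparsity pattern of the equality-constraint Jacobian.

    Defect block i is nonzero w.r.t. x_i (diagonal, the -I/dt term) and
    dense w.r.t. (x_{i+1}, u_{i+1}); boundary rows touch only the first and
    last node columns.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    blk = nx + nu
    rows, cols = [], []

    def col_x(node, k):
        return node * blk + k

    def col_u(node, k):
        return node * blk + nx + k

    for i in range(n - 1):
        r0 = i * nx
        for k in range(nx):
            rows.append(r0 + k)
            cols.append(col_x(i, k))            # -I/dt diagonal
        for k in range(nx):
            for j in range(nx):
                rows.append(r0 + k)
                cols.append(col_x(i + 1, j))    # I/dt - df/dx, dense
            for j in range(nu):
                rows.append(r0 + k)
                cols.append(col_u(i + 1, j))    # -df/du, dense
    rb = (n - 1) * nx
    r = rb
    for k in range(nx):
        if k == crank_index:
            continue
        rows += [r, r]
        cols += [col_x(0, k), col_x(n - 1, k)]
        r += 1
    for k in range(nu):
        rows += [r, r]
        cols += [col_u(0, k), col_u(n - 1, k)]
        r += 1
    rows.append(r)
    cols.append(col_x(0, crank_index))
    rows.append(r + 1)
    cols.append(col_x(n - 1, crank_index))
    n_rows = (n - 1) * nx + (nx - 1) + nu + 2
    data = np.ones(len(rows), bool)
    return sp.csc_matrix((data, (rows, cols)), shape=(n_rows, n * blk))


def color_columns(pattern: sp.csc_matrix) -> list[np.ndarray]:
    """Greedy structural-orthogonality coloring of the Jacobian columns.

    Columns in one group share no constraint row, so a single perturbed
    evaluation recovers all of their entries (Curtis-Powell-Reid).
    """
    pattern = pattern.tocsc()
    n_rows, n_cols = pattern.shape
    groups: list[list[int]] = []
    occupancy: list[np.ndarray] = []
    indptr, indices = pattern.indptr, pattern.indices
    for j in range(n_cols):
        rows_j = indices[indptr[j]:indptr[j + 1]]
        for g, occ in enumerate(occupancy):
            if not occ[rows_j].any():
                groups[g].append(j)
                occ[rows_j] = True
                break
        else:
            occ = np.zeros(n_rows, bool)
            occ[rows_j] = True
            occupancy.append(occ)
            groups.append([j])
    return [np.array(g, int) for g in groups]


def fd_jacobian(constraints, z: np.ndarray, pattern: sp.csc_matrix,
                groups: list[np.ndarray] | None = None, scheme: str = "forward",
                base: np.ndarray | None = None, rel_step: float = 1e-6,
                counter: list | None = None) -> sp.csr_matrix:
    """Sparse finite-difference Jacobian via grouped (colored) perturbations.

    ``counter``, when given, accumulates the number of constraint
    evaluations performed (list with one int).
    """
    z = np.asarray(z, float)
    pattern = pattern.tocsc()
    if groups is None:
        groups = color_columns(pattern)
    if base is None and scheme == "forward":
        base = np.asarray(constraints(z), float)
        if counter is not None:
            counter[0] += 1
    indptr, indices = pattern.indptr, pattern.indices
    J = sp.lil_matrix(pattern.shape)
    for group in groups:
        h = rel_step * (1.0 + np.abs(z[group]))
        dz = np.zeros_like(z)
        dz[group] = h
        if scheme == "forward":
            diff = np.asarray(constraints(z + dz), float) - base
            denom = h
            if counter is not None:
                counter[0] += 1
        else:
            diff = (np.asarray(constraints(z + dz), float)
                    - np.asarray(constraints(z - dz), float))
            denom = 2.0 * h
            if counter is not None:
                counter[0] += 2
        if not np.all(np.isfinite(diff)):
            bad = group[0]
            raise FloatingPointError(f"non-finite FD column near column {bad}")
        for jj, col in enumerate(group):
            rows_j = indices[indptr[col]:indptr[col + 1]]
            J[rows_j, col] = diff[rows_j] / denom[jj]
    return J.tocsr()


# -- problem assembly ---------------------------------------------------------

class NLPProblem:
    """The transcribed NLP in the standard solver callback contract.

    Exposes ``objective(z)``, ``gradient(z)``, ``constraints(z)``,
    ``jacobian(z)`` (sparse), ``jacobianstructure()`` and box bounds, with
    node-major decision layout [x_1, u_1, ..., x_n, u_n].  The sparsity
    pattern and its coloring are built lazily on first Jacobian use.
    """

    def __init__(self, model, target: TrackingTarget, weights: ObjectiveWeights,
                 n: int, tFinal: float, pattern: sp.csc_matrix | None = None,
                 groups: list | None = None, fd_scheme: str = "forward"):
        if n < 2:
            raise ValueError("n must be >= 2")
        self.model = model
        self.weights = weights
        self.n = n
        self.tFinal = tFinal
        self.fd_scheme = fd_scheme
        self.eval_counter = [0]
        self.nx, self.nu = model.nx, model.nu
        self.n_decision = (self.nx + self.nu) * n
        self.n_constraints = self.nx * (n - 1) + (self.nx - 1) + self.nu + 2
        self.target = target.resample(n)
        self._pattern = pattern
        self._groups = groups

    @property
    def pattern(self) -> sp.csc_matrix:
        if self._pattern is None:
            self._pattern = jacobian_sparsity(self.n, self.nx, self.nu,
                                              self.model.crank_angle_index)
        return self._pattern

    @property
    def groups(self) -> list:
        if self._groups is None:
            self._groups = color_columns(self.pattern)
        return self._groups

    # -- helpers
    def unpack(self, z) -> Trajectory:
        return Trajectory.unpack(z, self.n, self.nx, self.nu, self.tFinal)

    # -- callbacks
    def objective_terms(self, z) -> tuple[float, float, float]:
        return objective(self.unpack(z), self.target, self.weights, self.model)

    def objective(self, z) -> float:
        return self.objective_terms(z)[0]

    def gradient(self, z) -> np.ndarray:
        """Objective gradient; tracking part by per-node FD over the posture
        coordinates, activation/effort part analytic."""
        from .config import N_MUS, N_Q
        from .models import MuscleModel
        traj = self.unpack(z)
        g = np.zeros(self.n_decision)
        blk = self.nx + self.nu
        n = self.n
        v = N_OUTPUTS
        w1, w2 = self.weights.w1, self.weights.w2
        if w1 > 0:
            for i in range(n):
                x = traj.states[i]
                y = self.model.outputs(x)
                r = (y - self.target.means[i]) / self.target.sds[i] ** 2
                # outputs depend only on the joint angles q = x[:N_Q]
                for k in range(N_Q):
                    h = 1e-7 * (1.0 + abs(x[k]))
                    xp = x.copy()
                    xp[k] += h
                    dy = (self.model.outputs(xp) - y) / h
                    g[i * blk + k] += w1 * 2.0 / (v * n) * float(r @ dy)
        if w2 > 0:
            if isinstance(self.model, MuscleModel):
                for i in range(n):
                    a = traj.states[i, 2 * N_Q:2 * N_Q + N_MUS]
                    g[i * blk + 2 * N_Q:i * blk + 2 * N_Q + N_MUS] += (
                        w2 * 3.0 * a ** 2 / (N_MUS * n))
            else:
                ts = self.model.cfg.torque_scale
                for i in range(n):
                    u = traj.controls[i]
                    g[i * blk + self.nx:(i + 1) * blk] += (
                        w2 * 3.0 * np.sign(u) * (np.abs(u) / ts) ** 2 / ts
                        / (self.nu * n))
        return g

    def constraints(self, z) -> np.ndarray:
        traj = self.unpack(z)
        return np.concatenate([
            defect_constraints(traj, self.model.f),
            boundary_constraints(traj, self.model.crank_angle_index),
        ])

    def jacobian(self, z) -> sp.csr_matrix:
        return fd_jacobian(self.constraints, np.asarray(z, float), self.pattern,
                           self.groups, scheme=self.fd_scheme,
                           counter=self.eval_counter)

    def jacobianstructure(self):
        coo = self.pattern.tocoo()
        return coo.row, coo.col

    # -- bounds
    def decision_bounds(self):
        xlo, xhi = self.model.state_bounds()
        ulo, uhi = self.model.control_bounds()
        lo = np.tile(np.concatenate([xlo, ulo]), self.n)
        hi = np.tile(np.concatenate([xhi, uhi]), self.n)
        return lo, hi


def build_nlp(model, target: TrackingTarget, weights: ObjectiveWeights,
              n: int, tFinal: float, fd_scheme: str = "forward") -> NLPProblem:
    """Assemble the transcribed NLP for ``model`` at ``n`` nodes."""
    return NLPProblem(model, target, weights, n, tFinal, fd_scheme=fd_scheme)
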