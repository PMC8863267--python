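"""Resistive crank torque estimation and application.

On a friction-braked or geared ergometer the crank feels a resistive torque
that varies over the cycle.  Given measured (or simulated) crank torque and
crank angle series, the resistive profile follows from the crank's angular
momentum balance::

    T_crank - T_resistive = I_eff * alpha_crank

with I_eff the effective crank/flywheel inertia reflected through the gear
ratio.  The profile is cycle-averaged onto crank-angle bins, smoothed, and
resampled to 21 equally spaced points over [0, 360) degrees, then applied
as a periodic torque about the crank axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

N_PROFILE_POINTS = 21


@dataclass
class CrankData:
    """Time series of crank angle (rad) and net crank torque (N m)."""

    time: np.ndarray
    crank_angle: np.ndarray
    crank_torque: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, float)
        self.crank_angle = np.asarray(self.crank_angle, float)
        self.crank_torque = np.asarray(self.crank_torque, float)
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if not (len(self.time) == len(self.crank_angle) == len(self.crank_torque)):
            raise ValueError("series lengths differ")


@dataclass
class ResistiveTorqueProfile:
    """Periodic resistive torque vs crank angle at 21 equally spaced points.

    Positive torques oppose positive (forward) crank rotation.
    """

    angles_deg: np.ndarray = field(
        default_factory=lambda: np.linspace(0.0, 360.0, N_PROFILE_POINTS, endpoint=False))
    torques_nm: np.ndarray = field(
        default_factory=lambda: np.zeros(N_PROFILE_POINTS))
    interpolation: str = "cubic"

    def __post_init__(self) -> None:
        self.angles_deg = np.asarray(self.angles_deg, float)
        self.torques_nm = np.asarray(self.torques_nm, float)
        if len(self.angles_deg) != len(self.torques_nm):
            raise ValueError("angle/torque lengths differ")
        self._spline = None

    def _periodic_spline(self) -> CubicSpline:
        if self._spline is None:
            xs = np.concatenate([self.angles_deg, [self.angles_deg[0] + 360.0]])
            ys = np.concatenate([self.torques_nm, [self.torques_nm[0]]])
            self._spline = CubicSpline(xs, ys, bc_type="periodic")
        return self._spline


def central_difference(series, dt: float) -> np.ndarray:
    """Central-difference derivative; one-sided at the endpoints."""
    x = np.asarray(series, float)
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if len(x) < 3:
        raise ValueError("need at least 3 samples")
    d = np.empty_like(x)
    d[1:-1] = (x[2:] - x[:-2]) / (2.0 * dt)
    d[0] = (x[1] - x[0]) / dt
    d[-1] = (x[-1] - x[-2]) / dt
    return d


def _moving_average_periodic(y: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return y
    k = window // 2
    ext = np.concatenate([y[-k:], y, y[:k]])
    kernel = np.ones(2 * k + 1) / (2 * k + 1)
    return np.convolve(ext, kernel, mode="valid")


def estimate_resistive_torque(data: CrankData, i_eff: float,
                              n_points: int = N_PROFILE_POINTS,
                              n_bins: int = 72, smooth_window: int = 5) -> ResistiveTorqueProfile:
    """Estimate the periodic resistive torque profile from crank data.

    T_resistive(theta) = T_crank - I_eff * alpha, cycle-averaged onto
    crank-angle bins, smoothed with a periodic moving average, and
    resampled to ``n_points`` equally spaced angles.
    """
    if i_eff <= 0:
        raise ValueError("i_eff must be > 0")
    t = data.time
    if data.crank_angle[-1] - data.crank_angle[0] < 2 * np.pi * 0.999:
        raise ValueError("crank data must span at least one full cycle")
    dt = float(np.mean(np.diff(t)))
    if np.max(np.abs(np.diff(t) - dt)) > 1e-6 * max(dt, 1e-12):
        raise ValueError("time samples must be uniform")
    omega = central_difference(data.crank_angle, dt)
    alpha = central_difference(omega, dt)
    t_res = data.crank_torque - i_eff * alpha

    theta = np.mod(np.degrees(data.crank_angle), 360.0)
    edges = np.linspace(0.0, 360.0, n_bins + 1)
    idx = np.clip(np.digitize(theta, edges) - 1, 0, n_bins - 1)
    sums = np.bincount(idx, weights=t_res, minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    filled = counts > 0
    if filled.sum() < n_bins:
        # interpolate empty bins periodically from the filled ones
        ang_f = centers[filled]
        val_f = sums[filled] / counts[filled]
        binned = np.interp(centers, np.concatenate([ang_f - 360, ang_f, ang_f + 360]),
                           np.tile(val_f, 3))
    else:
        binned = sums / counts
    smooth = _moving_average_periodic(binned, smooth_window)

    out_angles = np.linspace(0.0, 360.0, n_points, endpoint=False)
    out = np.interp(out_angles, np.concatenate([centers - 360, centers, centers + 360]),
                    np.tile(smooth, 3))
    return ResistiveTorqueProfile(out_angles, out)


def resistive_torque_at(profile: ResistiveTorqueProfile, crank_angle) -> np.ndarray | float:
    """Periodic interpolation of the profile at crank angle(s) in radians."""
    theta = np.mod(np.degrees(np.asarray(crank_angle, float)), 360.0)
    a = profile.angles_deg
    v = profile.torques_nm
    if profile.interpolation == "linear":
        out = np.interp(theta, np.concatenate([a - 360, a, a + 360]), np.tile(v, 3))
    else:
        out = profile._periodic_spline()(theta)
    return float(out) if np.isscalar(crank_angle) or np.ndim(crank_angle) == 0 else out
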