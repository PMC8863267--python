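"""Figure generation: tracking quality and excitation patterns.

Layouts follow the field's convention: pedal angle and the two pedal-force
components versus crank angle with the target mean and a +/-1 SD band, and
a grid of MTU excitations versus crank angle.
"""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .config import ModelConfig  # noqa: E402
from .models import tracked_outputs  # noqa: E402
from .transcription import TrackingTarget, Trajectory  # noqa: E402


def plot_tracking(cfg: ModelConfig, traj: Trajectory, target: TrackingTarget,
                  path, side: str = "L") -> None:
    """Pedal angle, Fx and Fy of one leg vs crank angle, with SD bands."""
    target = target.resample(traj.n)
    outputs = np.array([tracked_outputs(cfg, x[:7]) for x in traj.states])
    crank_deg = np.degrees(traj.states[:, 6])
    cols = {"L": (0, 2, 3), "R": (1, 4, 5)}[side]
    labels = ("pedal angle (deg)", "pedal force x (N)", "pedal force y (N)")
    fig, axes = plt.subplots(3, 1, figsize=(6, 8), sharex=True)
    for ax, k, lab in zip(axes, cols, labels):
        ax.fill_between(crank_deg, target.means[:, k] - target.sds[:, k],
                        target.means[:, k] + target.sds[:, k],
                        color="0.8", label="target ±1 SD")
        ax.plot(crank_deg, target.means[:, k], color="0.4", label="target mean")
        ax.plot(crank_deg, outputs[:, k], "r-", label="simulated")
        ax.set_ylabel(lab)
    axes[0].legend(loc="best", fontsize=8)
    axes[-1].set_xlabel("crank angle (deg)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_excitations(cfg: ModelConfig, traj: Trajectory, path,
                     side: str = "L") -> None:
    """Grid of control signals vs crank angle (excitations or torques)."""
    crank_deg = np.degrees(traj.states[:, 6])
    nu = traj.controls.shape[1]
    if nu == 18:
        labels = [m.label for m in cfg.mtus]
        keep = [i for i, lab in enumerate(labels) if lab.endswith(f"_{side}")]
    else:
        labels = [f"tau_{j}_{s}" for s in ("L", "R") for j in ("hip", "knee", "ankle")]
        keep = list(range(nu))
    ncols = 3
    nrows = -(-len(keep) // ncols)
    fig, axes = plt.subplots(nrows, ncols, figsize=(9, 2.2 * nrows),
                             sharex=True, squeeze=False)
    for ax, i in zip(axes.ravel(), keep):
        ax.plot(crank_deg, traj.controls[:, i], "k-")
        ax.set_title(labels[i], fontsize=9)
    for ax in axes.ravel()[len(keep):]:
        ax.axis("off")
    for ax in axes[-1]:
        ax.set_xlabel("crank angle (deg)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
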