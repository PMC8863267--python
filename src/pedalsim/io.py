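"""Readers and writers: STO/MOT motion tables, target tables, reports.

Motion files use the OpenSim storage dialect: a small ``key=value`` header
terminated by ``endheader``, then a tab-delimited table whose first column
is time.  Angles are stored in degrees when the header says
``inDegrees=yes`` and converted to radians on read for the columns the
caller declares angular.  Trajectories round-trip through
:func:`write_trajectory_sto` / :func:`read_trajectory_sto` with canonical
column names.
"""

from __future__ import annotations

import json
from datetime import datetime, timezone

import numpy as np
import pandas as pd

from . import __version__
from .config import LEG_JOINTS, N_MUS, N_Q, ModelConfig
from .models import OUTPUT_NAMES
from .transcription import TrackingTarget, Trajectory

Q_NAMES = [f"q_{j}_{s}" for s in ("L", "R") for j in LEG_JOINTS] + ["q_crank"]
QDOT_NAMES = [n.replace("q_", "qdot_", 1) for n in Q_NAMES]


# -- STO/MOT -------------------------------------------------------------------

def write_sto(path, df: pd.DataFrame, name: str = "pedalsim",
              in_degrees: bool = True, comments: dict | None = None) -> None:
    """Write a time-indexed table in the STO dialect (no unit conversion)."""
    n_rows, n_cols = df.shape
    with open(path, "w") as fh:
        fh.write(f"{name}\n")
        fh.write("version=1\n")
        for k, v in (comments or {}).items():
            fh.write(f"{k}={v}\n")
        fh.write(f"nRows={n_rows}\n")
        fh.write(f"nColumns={n_cols}\n")
        fh.write(f"inDegrees={'yes' if in_degrees else 'no'}\n")
        fh.write("endheader\n")
        fh.write("\t".join(df.columns) + "\n")
        for _, row in df.iterrows():
            fh.write("\t".join(f"{v:.12g}" for v in row.values) + "\n")


def read_sto(path):
    """Read an STO/MOT table; returns ``(DataFrame, header dict)``.

    Raises ``ValueError`` naming the offending line for malformed headers
    or row-count mismatches.
    """
    with open(path) as fh:
        lines = fh.readlines()
    header = {}
    body_start = None
    for i, line in enumerate(lines[1:], start=2):
        s = line.strip()
        if s == "endheader":
            body_start = i
            break
        if "=" in s:
            k, v = s.split("=", 1)
            header[k.strip()] = v.strip()
    if body_start is None:
        raise ValueError(f"{path}: no 'endheader' line found")
    for key in ("nRows", "nColumns"):
        if key not in header:
            raise ValueError(f"{path}: header missing {key}")
    columns = lines[body_start].rstrip("\n").split("\t")
    n_cols = int(header["nColumns"])
    if len(columns) != n_cols:
        raise ValueError(f"{path}: line {body_start + 1}: {len(columns)} columns, "
                         f"header says {n_cols}")
    rows = []
    for ln, line in enumerate(lines[body_start + 1:], start=body_start + 2):
        if not line.strip():
            continue
        vals = line.split()
        if len(vals) != n_cols:
            raise ValueError(f"{path}: line {ln}: {len(vals)} values, expected {n_cols}")
        rows.append([float(v) for v in vals])
    n_rows = int(header["nRows"])
    if len(rows) != n_rows:
        raise ValueError(f"{path}: {len(rows)} data rows, header says nRows={n_rows}")
    df = pd.DataFrame(rows, columns=columns)
    header["inDegrees"] = header.get("inDegrees", "no").lower()
    return df, header


def write_trajectory_sto(path, traj: Trajectory, model_kind: str = "muscle",
                         cfg: ModelConfig | None = None,
                         provenance: dict | None = None) -> None:
    """Serialize a trajectory (angles in degrees in the file)."""
    n = traj.n
    cols = {"time": traj.times}
    states = traj.states
    for i, name in enumerate(Q_NAMES):
        cols[name] = np.degrees(states[:, i])
    for i, name in enumerate(QDOT_NAMES):
        cols[name] = np.degrees(states[:, N_Q + i])
    if model_kind == "muscle":
        labels = ([m.label for m in cfg.mtus] if cfg is not None
                  else [f"mtu{i}" for i in range(N_MUS)])
        for i, lab in enumerate(labels):
            cols[f"act_{lab}"] = states[:, 2 * N_Q + i]
        for i, lab in enumerate(labels):
            cols[f"lcc_{lab}"] = states[:, 2 * N_Q + N_MUS + i]
        for i, lab in enumerate(labels):
            cols[f"u_{lab}"] = traj.controls[:, i]
    else:
        tq = [f"tau_{j}_{s}" for s in ("L", "R") for j in LEG_JOINTS]
        for i, name in enumerate(tq):
            cols[name] = traj.controls[:, i]
    df = pd.DataFrame(cols)
    comments = {"tFinal": f"{traj.tFinal:.12g}", "modelKind": model_kind}
    comments.update(provenance or {})
    write_sto(path, df, name="pedalsim_trajectory", in_degrees=True,
              comments=comments)


def read_trajectory_sto(path) -> Trajectory:
    df, header = read_sto(path)
    tFinal = float(header.get("tFinal", df["time"].iloc[-1]))
    deg = header["inDegrees"] == "yes"
    conv = np.radians if deg else (lambda x: x)
    states = [conv(df[n].values) for n in Q_NAMES]
    states += [conv(df[n].values) for n in QDOT_NAMES]
    act_cols = [c for c in df.columns if c.startswith("act_")]
    if act_cols:
        lcc_cols = [c.replace("act_", "lcc_", 1) for c in act_cols]
        u_cols = [c.replace("act_", "u_", 1) for c in act_cols]
        states += [df[c].values for c in act_cols]
        states += [df[c].values for c in lcc_cols]
        controls = np.column_stack([df[c].values for c in u_cols])
    else:
        tq = [f"tau_{j}_{s}" for s in ("L", "R") for j in LEG_JOINTS]
        controls = np.column_stack([df[c].values for c in tq])
    return Trajectory(tFinal, np.column_stack(states), controls)


def write_muscle_diagnostics_sto(path, cfg: ModelConfig, traj: Trajectory,
                                 provenance: dict | None = None) -> None:
    """Per-muscle diagnostic series: tendon force, CC length, activation."""
    from .muscle import mtu_forces
    cols = {"time": traj.times}
    labels = [m.label for m in cfg.mtus]
    forces = np.array([mtu_forces(cfg, x[:N_Q], x[2 * N_Q + N_MUS:])
                       for x in traj.states])
    for i, lab in enumerate(labels):
        cols[f"force_{lab}"] = forces[:, i]
    for i, lab in enumerate(labels):
        cols[f"lcc_{lab}"] = traj.states[:, 2 * N_Q + N_MUS + i]
    for i, lab in enumerate(labels):
        cols[f"act_{lab}"] = traj.states[:, 2 * N_Q + i]
    write_sto(path, pd.DataFrame(cols), name="pedalsim_muscle_diagnostics",
              in_degrees=False, comments=provenance)


# -- crank data tables ---------------------------------------------------------

def write_crank_data_csv(path, data, provenance: dict | None = None) -> None:
    """Crank time/angle/torque series as a delimited table (angle in deg)."""
    df = pd.DataFrame({"time": data.time,
                       "crank_angle_deg": np.degrees(data.crank_angle),
                       "crank_torque_nm": data.crank_torque})
    with open(path, "w") as fh:
        for k, v in (provenance or {}).items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, index=False, float_format="%.10g")


def read_crank_data_csv(path):
    from .crankload import CrankData
    df = pd.read_csv(path, comment="#")
    return CrankData(df["time"].values,
                     np.radians(df["crank_angle_deg"].values),
                     df["crank_torque_nm"].values)


# -- tracking-target tables ----------------------------------------------------

def write_target_csv(path, target: TrackingTarget, tFinal: float,
                     provenance: dict | None = None) -> None:
    """Target schema: node, time, the 6 tracked variables, matching sd_ columns."""
    n = target.n
    df = pd.DataFrame({"node": np.arange(n),
                       "time": np.linspace(0.0, tFinal, n)})
    for k, name in enumerate(target.names):
        df[name] = target.means[:, k]
    for k, name in enumerate(target.names):
        df[f"sd_{name}"] = target.sds[:, k]
    with open(path, "w") as fh:
        for k, v in (provenance or {}).items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, index=False, float_format="%.10g")


def read_target_csv(path):
    """Returns ``(TrackingTarget, tFinal)``."""
    df = pd.read_csv(path, comment="#")
    means = np.column_stack([df[name].values for name in OUTPUT_NAMES])
    sds = np.column_stack([df[f"sd_{name}"].values for name in OUTPUT_NAMES])
    return TrackingTarget(means, sds), float(df["time"].iloc[-1])


# -- reports -------------------------------------------------------------------

def provenance_stamp(cfg: ModelConfig | None = None, seed: int | None = None) -> dict:
    stamp = {"tool": "pedalsim", "version": __version__,
             "created": datetime.now(timezone.utc).isoformat(timespec="seconds")}
    if cfg is not None:
        stamp["config_digest"] = cfg.digest()
    if seed is not None:
        stamp["seed"] = seed
    return stamp


def write_report_json(path, report, cfg: ModelConfig | None = None,
                      seed: int | None = None, extra: dict | None = None) -> None:
    doc = {"provenance": provenance_stamp(cfg, seed)}
    doc["report"] = report.as_dict() if hasattr(report, "as_dict") else report
    if extra:
        doc.update(extra)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, default=float)
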