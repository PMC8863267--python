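"""Model configuration for the planar bicycle-rider system.

The model is a sagittal-plane, seated-pedaling system: a fixed pelvis, two
three-segment legs (thigh, shank, foot) hanging from a common hip point, and
a crank rotating about a fixed axis.  Each foot is coupled to its pedal by a
stiff point-to-point spring at the distal end of the metatarsals, which
closes the kinematic loop softly and provides the pedal-force readout.
Eighteen muscle-tendon units (nine per leg) actuate the hip, knee and ankle
joints.

All angles are stored in radians internally; file formats use degrees.
World frame: origin at the crank axis, x anterior-positive, y up-positive.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field

import numpy as np
import yaml

#: names of the nine muscle-tendon units per leg
MTU_NAMES = ("IP", "GMAX", "VAS", "RF", "HAM", "BFsh", "GAS", "SOL", "TA")
#: joint names within one leg, in generalized-coordinate order
LEG_JOINTS = ("hip", "knee", "ankle")
#: sides, in generalized-coordinate order (left leg first, then right)
SIDES = ("L", "R")

N_Q = 7          # generalized coordinates: L hip/knee/ankle, R hip/knee/ankle, crank
N_MUS = 18       # muscle-tendon units
N_STATES = 2 * N_Q + 2 * N_MUS   # 50
CRANK_INDEX = 6  # index of the crank angle within q


@dataclass
class SegmentParams:
    """Inertial parameters of one rigid segment.

    ``com_offset`` is measured from the proximal joint along the segment
    axis; ``inertia_com`` is the moment of inertia about the center of mass,
    normal to the sagittal plane.
    """

    name: str
    mass: float
    length: float
    com_offset: float
    inertia_com: float

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError(f"segment {self.name}: mass must be > 0")
        if self.length <= 0:
            raise ValueError(f"segment {self.name}: length must be > 0")
        if self.inertia_com < 0:
            raise ValueError(f"segment {self.name}: inertia_com must be >= 0")
        if not 0.0 <= self.com_offset <= self.length:
            raise ValueError(f"segment {self.name}: com_offset outside [0, length]")


@dataclass
class MTUParams:
    """Parameters of one Hill-type muscle-tendon unit.

    The musculoskeletal path is encoded as per-joint moment-arm polynomials
    ``arms[joint] = [c0, c1, ...]`` giving r(theta) = sum c_k theta^k in
    meters (theta in radians, signed so that positive r produces torque in
    the positive joint-angle direction).  MTU length follows from the
    reference length ``l_ref`` at the reference posture ``q_ref`` by
    integrating the moment arms: l(q) = l_ref - sum_j int_{ref}^{theta_j} r_j.
    """

    name: str
    side: str                      # "L" or "R"
    fmax: float                    # maximum isometric force, N
    lcc_opt: float                 # optimal contractile-component length, m
    l_slack_sec: float             # series-elastic slack length, m
    vmax: float = 10.0             # max shortening velocity, lcc_opt/s
    act_tau: float = 0.015         # activation time constant, s
    deact_tau: float = 0.060       # deactivation time constant, s
    fv_shape: float = 0.25         # Hill a/F0 shape constant
    ecc_plateau: float = 1.45      # eccentric force asymptote, /fmax
    fl_width: float = 0.25         # Gaussian force-length width
    sec_strain_ref: float = 0.04   # SEC strain at fmax
    pec_norm_width: float = 0.6    # PEC normalized stretch at fmax
    arms: dict = field(default_factory=dict)   # joint -> ascending poly coeffs
    l_ref: float = 0.0             # MTU length at q_ref, m
    q_ref: dict = field(default_factory=dict)  # joint -> reference angle, rad

    def __post_init__(self) -> None:
        if self.fmax <= 0 or self.lcc_opt <= 0 or self.vmax <= 0:
            raise ValueError(f"MTU {self.name}: fmax, lcc_opt, vmax must be > 0")
        if self.l_slack_sec < 0:
            raise ValueError(f"MTU {self.name}: l_slack_sec must be >= 0")
        if self.side not in SIDES:
            raise ValueError(f"MTU {self.name}: side must be L or R")

    @property
    def label(self) -> str:
        return f"{self.name}_{self.side}"


@dataclass
class ModelConfig:
    """Full physical parameterization of the bicycle-rider model."""

    segments: dict = field(default_factory=dict)      # name -> SegmentParams
    pelvis_tilt_deg: float = 11.5
    pelvis_center: tuple = (-0.15, 0.69)              # m, world (crank axis at origin)
    hip_in_pelvis: tuple = (0.0, -0.07)               # m, pelvis frame
    crank_arm_length: float = 0.17                    # m
    crank_inertia_eff: float = 23.53                  # kg m^2, lumped flywheel/gear inertia
    spring_k: float = 100000.0                        # N/m foot-pedal coupling
    spring_rest_length: float = 0.0                   # m
    spring_damping: float = 0.0                       # N s/m
    pedal_angle_offset_deg: float = 12.5              # reporting offset
    toe_from_ankle: float = 0.165                     # m along foot axis
    heel_from_ankle: float = -0.075
    meta_from_ankle: float = 0.135                    # spring attachment (metatarsals)
    foot_com_from_ankle: float = 0.05
    gravity: float = 9.81
    tFinal: float = 1.914                             # crank cycle duration, s
    mtus: list = field(default_factory=list)          # 18 MTUParams
    resistive_profile: dict = field(default_factory=dict)  # angles_deg, torques_nm
    knee_coupling: dict | None = None                 # optional {x: coeffs, y: coeffs}
    angle_bounds: dict = field(default_factory=dict)  # joint -> (lo, hi) rad
    velocity_bound: float = 30.0                      # rad/s, symmetric
    torque_bound: float = 300.0                       # N m, reduced-mode control bound
    torque_scale: float = 150.0                       # N m, effort normalization

    def __post_init__(self) -> None:
        if self.spring_k <= 0:
            raise ValueError("spring_k must be > 0")
        if self.crank_inertia_eff <= 0:
            raise ValueError("crank_inertia_eff must be > 0")
        if self.tFinal <= 0:
            raise ValueError("tFinal must be > 0")
        if self.mtus and len(self.mtus) != N_MUS:
            raise ValueError(f"expected {N_MUS} MTUs, got {len(self.mtus)}")

    # -- convenience geometry -------------------------------------------------
    @property
    def hip_position(self) -> np.ndarray:
        """World coordinates of the (shared) hip joint center."""
        t = math.radians(self.pelvis_tilt_deg)
        c, s = math.cos(t), math.sin(t)
        ox, oy = self.hip_in_pelvis
        px, py = self.pelvis_center
        return np.array([px + c * ox - s * oy, py + s * ox + c * oy])

    def mtu_index(self, label: str) -> int:
        for i, m in enumerate(self.mtus):
            if m.label == label:
                return i
        raise KeyError(label)

    def digest(self) -> str:
        """Short content hash used for provenance stamps in outputs."""
        blob = json.dumps(to_dict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


# moment-arm polynomials, ascending coefficients (m per rad^k); signed so
# positive r gives torque toward positive joint angle (flexion-positive hip
# and knee angles, dorsiflexion-positive ankle)
_DEFAULT_MTUS = {
    # name: (fmax, lcc_opt, l_slack, {joint: coeffs})
    "IP":   (1500.0, 0.100, 0.090, {"hip": [0.050]}),
    "GMAX": (1550.0, 0.140, 0.125, {"hip": [-0.062]}),
    "VAS":  (4500.0, 0.093, 0.223, {"knee": [-0.048, 0.006]}),
    "RF":   (1200.0, 0.081, 0.346, {"hip": [0.034], "knee": [-0.040]}),
    "HAM":  (2200.0, 0.104, 0.334, {"hip": [-0.062], "knee": [0.038, -0.006]}),
    "BFsh": (350.0, 0.173, 0.089, {"knee": [0.032]}),
    "GAS":  (1600.0, 0.060, 0.390, {"knee": [0.016], "ankle": [-0.042]}),
    "SOL":  (3600.0, 0.055, 0.250, {"ankle": [-0.048]}),
    "TA":   (900.0, 0.082, 0.220, {"ankle": [0.037]}),
}

# representative mid-cycle posture used to anchor MTU reference lengths
_Q_REF = {"hip": 0.8, "knee": 1.3, "ankle": -0.1}


def default_config() -> ModelConfig:
    """Representative anthropometry for a ~67 kg, 1.70 m rider.

    Segment masses, lengths and inertias follow standard proportional
    anthropometric tables; muscle parameters are literature-style planar
    values.  Every value can be overridden via the YAML config file.
    """
    segments = {
        "pelvis": SegmentParams("pelvis", 35.0, 0.15, 0.075, 0.30),
        "thigh": SegmentParams("thigh", 7.0, 0.43, 0.187, 0.115),
        "shank": SegmentParams("shank", 3.0, 0.42, 0.182, 0.048),
        "foot": SegmentParams("foot", 1.0, 0.24, 0.120, 0.0045),
        "crank": SegmentParams("crank", 2.0, 0.17, 0.0, 0.02),
    }
    mtus = []
    for side in SIDES:
        for name in MTU_NAMES:
            fmax, lopt, slack, arms = _DEFAULT_MTUS[name]
            q_ref = {j: _Q_REF[j] for j in arms}
            mtus.append(MTUParams(
                name=name, side=side, fmax=fmax, lcc_opt=lopt,
                l_slack_sec=slack, arms={j: list(c) for j, c in arms.items()},
                l_ref=lopt + slack, q_ref=q_ref,
            ))
    angles = np.linspace(0.0, 360.0, 21, endpoint=False)
    cfg = ModelConfig(
        segments=segments,
        mtus=mtus,
        resistive_profile={
            "angles_deg": angles.tolist(),
            "torques_nm": [9.1] * 21,
        },
        angle_bounds={
            "hip": (-0.6, 2.6),
            "knee": (0.0, 2.9),
            "ankle": (-1.2, 1.2),
            "crank": (-0.8, 2 * math.pi + 0.8),
        },
    )
    return cfg


# -- serialization ------------------------------------------------------------

def to_dict(cfg: ModelConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["segments"] = {k: dataclasses.asdict(v) for k, v in cfg.segments.items()}
    d["mtus"] = [dataclasses.asdict(m) for m in cfg.mtus]
    return d


def from_dict(d: dict) -> ModelConfig:
    d = dict(d)
    d["segments"] = {k: SegmentParams(**v) for k, v in d.get("segments", {}).items()}
    d["mtus"] = [MTUParams(**m) for m in d.get("mtus", [])]
    for key in ("pelvis_center", "hip_in_pelvis"):
        if key in d:
            d[key] = tuple(d[key])
    return ModelConfig(**d)


def save_config(cfg: ModelConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(to_dict(cfg), fh, sort_keys=False)


def load_config(path) -> ModelConfig:
    with open(path) as fh:
        return from_dict(yaml.safe_load(fh))
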