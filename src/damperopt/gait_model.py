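"""Reduced-order planar gait model: parametric kinematics + inverse dynamics.

This module is a desk-scale stand-in for a forward-dynamics neuromuscular
simulation.  Gait is prescribed as truncated Fourier series on the hip,
knee, and ankle angles of one leg (the other leg runs half a stride out of
phase) plus a pelvis trajectory.  A planar Newton-Euler recursion over
each leg then recovers every quantity the design costs need: net and
biological joint moments, intersegmental knee force, ground reaction
forces, joint powers, a metabolic-power proxy, and the normalized knee
load.

Conventions
-----------
* Sagittal plane, x forward (walking direction), y up, z out of plane.
* Knee angle 0 at full extension, flexion positive; hip flexion positive
  (thigh forward of vertical); ankle dorsiflexion positive.
* Joint moments are reported flexion-positive (dorsiflexion-positive at
  the ankle), so joint power = moment * joint angular velocity.
* The device torque is a pure couple between thigh and shank; it does not
  alter the prescribed motion, so the net joint moment splits as
  ``biological = net - exo`` at every sample.
* Downhill scenarios rotate the ground plane (``y_ground = tan(slope)*x``)
  while gravity stays vertical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from damperopt.device import DesignParams, damper_torque
from damperopt.phases import (
    GaitPhase,
    LegState,
    NoStrideError,
    PhaseThresholds,
    detect_strides,
    label_phases,
)

__all__ = [
    "Anthropometry",
    "ScenarioConfig",
    "ControllerTheta",
    "Kinematics",
    "InverseDynamicsResult",
    "SimResult",
    "default_anthropometry",
    "theta_to_json",
    "theta_from_json",
    "fourier_eval",
    "generate_kinematics",
    "inverse_dynamics",
    "knee_load",
    "metabolic_power",
    "simulate",
]

LEGS = ("right", "left")


# --------------------------------------------------------------------------
# configuration types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Anthropometry:
    """Planar segment parameters: trunk + per-leg thigh, shank, point foot.

    Thigh and shank are uniform rods (CoM at midpoint, I = m l^2 / 12);
    the foot is a point mass offset from the ankle.  Trunk CoM rides at a
    fixed offset above the pelvis.
    """

    total_mass: float = 75.0
    trunk_mass: float = 50.85
    thigh_mass: float = 7.5
    shank_mass: float = 3.4875
    foot_mass: float = 1.0875
    thigh_length: float = 0.44
    shank_length: float = 0.43
    foot_length: float = 0.10
    trunk_com_height: float = 0.30
    device_thigh_mass: float = 0.0  # attachment masses, lumped into segments
    device_shank_mass: float = 0.0

    def __post_init__(self) -> None:
        seg_sum = self.trunk_mass + 2 * (
            self.thigh_mass + self.shank_mass + self.foot_mass
        )
        if abs(seg_sum - self.total_mass) > 1e-6 * max(1.0, self.total_mass):
            raise ValueError(
                f"segment masses sum to {seg_sum}, expected total {self.total_mass}"
            )
        for name in ("thigh_length", "shank_length", "foot_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def body_weight(self) -> float:
        return self.total_mass * 9.81

    @property
    def leg_length(self) -> float:
        return self.thigh_length + self.shank_length


def default_anthropometry(total_mass: float = 75.0) -> Anthropometry:
    """Scale the default segment masses to a given total body mass."""
    f = total_mass / 75.0
    return Anthropometry(
        total_mass=total_mass,
        trunk_mass=50.85 * f,
        thigh_mass=7.5 * f,
        shank_mass=3.4875 * f,
        foot_mass=1.0875 * f,
    )


@dataclass(frozen=True)
class ScenarioConfig:
    """Gait scenario: slope, target speed, duration, integration grid."""

    slope_deg: float = 0.0
    target_speed: float = 1.2
    duration: float = 10.0
    dt: float = 0.005
    gravity: float = 9.81
    speed_tolerance: float = 0.05
    name: str = "level"

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.dt <= 0:
            raise ValueError("duration and dt must be > 0")

    @property
    def slope_rad(self) -> float:
        return np.deg2rad(self.slope_deg)

    @property
    def ground_grade(self) -> float:
        """dy/dx of the ground plane (negative = downhill for +x walking)."""
        return float(np.tan(self.slope_rad))

    def time_grid(self) -> np.ndarray:
        n = int(round(self.duration / self.dt))
        return np.arange(n) * self.dt


# layout of the flat optimization vector: three joints with `n_harmonics`
# cosine/sine pairs plus a constant, then the scalar gait parameters
_JOINTS = ("hip", "knee", "ankle")


@dataclass(frozen=True)
class ControllerTheta:
    """Parametric gait: per-joint Fourier coefficients + scalar gait terms.

    Coefficient layout per joint is ``[a0, a1, b1, a2, b2, ...]`` for
    ``theta(t) = a0 + sum_k a_k cos(2 pi k t / T) + b_k sin(2 pi k t / T)``.
    Both legs share the coefficients; the left leg is phase-shifted by half
    a stride.  ``stance_load_threshold`` is carried here because the inner
    loop optimizes it along with the gait shape.
    """

    hip_coeffs: tuple
    knee_coeffs: tuple
    ankle_coeffs: tuple
    stride_period: float = 1.1
    stride_length: float = 1.32
    pelvis_height: float = 0.86
    pelvis_vert_amp: float = 0.01
    pelvis_vert_phase: float = 0.0
    pelvis_fore_amp: float = 0.0
    pelvis_fore_phase: float = 0.0
    stance_load_threshold: float = 0.2

    def __post_init__(self) -> None:
        for name in ("hip_coeffs", "knee_coeffs", "ankle_coeffs"):
            coeffs = tuple(float(v) for v in getattr(self, name))
            if len(coeffs) % 2 != 1:
                raise ValueError(f"{name} must have odd length [a0, a1, b1, ...]")
            if not np.all(np.isfinite(coeffs)):
                raise ValueError(f"{name} contains non-finite values")
            object.__setattr__(self, name, coeffs)
        if not np.isfinite(self.stride_period) or self.stride_period <= 0:
            raise ValueError("stride_period must be > 0")
        if self.stride_length <= 0:
            raise ValueError("stride_length must be > 0")

    @property
    def speed(self) -> float:
        """Mean forward speed implied by stride length and period."""
        return self.stride_length / self.stride_period

    # -- flat-vector interface for the inner optimizer ---------------------

    _SCALARS = (
        "stride_period",
        "stride_length",
        "pelvis_height",
        "pelvis_vert_amp",
        "pelvis_vert_phase",
        "pelvis_fore_amp",
        "pelvis_fore_phase",
        "stance_load_threshold",
    )

    def to_vector(self) -> np.ndarray:
        parts = [self.hip_coeffs, self.knee_coeffs, self.ankle_coeffs]
        parts.append([getattr(self, s) for s in self._SCALARS])
        return np.concatenate([np.asarray(p, dtype=float) for p in parts])

    def from_vector(self, vec: np.ndarray) -> "ControllerTheta":
        """Rebuild a theta with this one's layout from a flat vector."""
        vec = np.asarray(vec, dtype=float)
        sizes = [len(self.hip_coeffs), len(self.knee_coeffs), len(self.ankle_coeffs)]
        if vec.size != sum(sizes) + len(self._SCALARS):
            raise ValueError(f"expected vector of size {sum(sizes) + len(self._SCALARS)}")
        i0, i1 = sizes[0], sizes[0] + sizes[1]
        i2 = i1 + sizes[2]
        scalars = dict(zip(self._SCALARS, vec[i2:]))
        scalars["stride_period"] = max(scalars["stride_period"], 1e-3)
        scalars["stride_length"] = max(scalars["stride_length"], 1e-3)
        scalars["stance_load_threshold"] = float(
            np.clip(scalars["stance_load_threshold"], 1e-3, 2.0)
        )
        return replace(
            self,
            hip_coeffs=tuple(vec[:i0]),
            knee_coeffs=tuple(vec[i0:i1]),
            ankle_coeffs=tuple(vec[i1:i2]),
            **scalars,
        )


def theta_to_json(theta: ControllerTheta, path) -> None:
    """Serialize a controller parameterization as JSON."""
    payload = {
        "hip_coeffs": list(theta.hip_coeffs),
        "knee_coeffs": list(theta.knee_coeffs),
        "ankle_coeffs": list(theta.ankle_coeffs),
    }
    payload.update({name: getattr(theta, name) for name in ControllerTheta._SCALARS})
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def theta_from_json(path) -> ControllerTheta:
    with open(path) as fh:
        payload = json.load(fh)
    return ControllerTheta(
        hip_coeffs=tuple(payload.pop("hip_coeffs")),
        knee_coeffs=tuple(payload.pop("knee_coeffs")),
        ankle_coeffs=tuple(payload.pop("ankle_coeffs")),
        **payload,
    )


# --------------------------------------------------------------------------
# kinematics
# --------------------------------------------------------------------------


def fourier_eval(
    coeffs: Sequence[float], t: np.ndarray, period: float, order: int = 0
) -> np.ndarray:
    """Evaluate a Fourier series ``[a0, a1, b1, ...]`` or its derivatives."""
    coeffs = np.asarray(coeffs, dtype=float)
    t = np.asarray(t, dtype=float)
    w0 = 2.0 * np.pi / period
    out = np.full_like(t, coeffs[0] if order == 0 else 0.0)
    n_harm = (len(coeffs) - 1) // 2
    for k in range(1, n_harm + 1):
        a, b = coeffs[2 * k - 1], coeffs[2 * k]
        wk = k * w0
        phase = wk * t
        if order == 0:
            out = out + a * np.cos(phase) + b * np.sin(phase)
        elif order == 1:
            out = out + wk * (-a * np.sin(phase) + b * np.cos(phase))
        elif order == 2:
            out = out + wk**2 * (-a * np.cos(phase) - b * np.sin(phase))
        else:
            raise ValueError("order must be 0, 1, or 2")
    return out


@dataclass
class Kinematics:
    """Joint-space trajectories on a shared time grid, both legs."""

    t: np.ndarray
    dt: float
    stride_period: float
    angles: dict  # angles[leg][joint] -> array, rad
    omegas: dict
    alphas: dict
    pelvis_pos: np.ndarray  # (n, 2)
    pelvis_vel: np.ndarray
    pelvis_acc: np.ndarray


def generate_kinematics(theta: ControllerTheta, scenario: ScenarioConfig) -> Kinematics:
    """Synthesize periodic joint and pelvis trajectories from ``theta``.

    The left leg replays the right leg's trajectories shifted by half a
    stride period.  All derivatives are analytic.
    """
    t = scenario.time_grid()
    T = theta.stride_period
    v = theta.speed
    grade = scenario.ground_grade

    angles: dict = {}
    omegas: dict = {}
    alphas: dict = {}
    for leg, shift in (("right", 0.0), ("left", T / 2.0)):
        ts = t + shift
        angles[leg] = {}
        omegas[leg] = {}
        alphas[leg] = {}
        for joint in _JOINTS:
            coeffs = getattr(theta, f"{joint}_coeffs")
            angles[leg][joint] = fourier_eval(coeffs, ts, T, 0)
            omegas[leg][joint] = fourier_eval(coeffs, ts, T, 1)
            alphas[leg][joint] = fourier_eval(coeffs, ts, T, 2)

    # pelvis: steady advance along the slope + twice-per-stride oscillation
    w2 = 4.0 * np.pi / T
    px = (
        v * t
        + theta.pelvis_fore_amp * np.sin(w2 * t + theta.pelvis_fore_phase)
    )
    py = (
        theta.pelvis_height
        + grade * v * t
        + theta.pelvis_vert_amp * np.cos(w2 * t + theta.pelvis_vert_phase)
    )
    vx = v + theta.pelvis_fore_amp * w2 * np.cos(w2 * t + theta.pelvis_fore_phase)
    vy = grade * v - theta.pelvis_vert_amp * w2 * np.sin(w2 * t + theta.pelvis_vert_phase)
    ax = -theta.pelvis_fore_amp * w2**2 * np.sin(w2 * t + theta.pelvis_fore_phase)
    ay = -theta.pelvis_vert_amp * w2**2 * np.cos(w2 * t + theta.pelvis_vert_phase)

    return Kinematics(
        t=t,
        dt=scenario.dt,
        stride_period=T,
        angles=angles,
        omegas=omegas,
        alphas=alphas,
        pelvis_pos=np.column_stack([px, py]),
        pelvis_vel=np.column_stack([vx, vy]),
        pelvis_acc=np.column_stack([ax, ay]),
    )


def _unit(angle_from_down: np.ndarray) -> np.ndarray:
    """Unit vector at `angle` measured from straight-down, CCW positive."""
    return np.column_stack([np.sin(angle_from_down), -np.cos(angle_from_down)])


def _leg_geometry(kin: Kinematics, anthro: Anthropometry, leg: str) -> dict:
    """Cartesian positions of joints and segment CoMs for one leg."""
    th_h = kin.angles[leg]["hip"]
    th_k = kin.angles[leg]["knee"]
    th_a = kin.angles[leg]["ankle"]
    theta_thigh = th_h  # from vertical-down, CCW+
    theta_shank = th_h - th_k
    theta_foot = theta_shank + np.pi / 2.0 + th_a

    hip = kin.pelvis_pos
    knee = hip + anthro.thigh_length * _unit(theta_thigh)
    ankle = knee + anthro.shank_length * _unit(theta_shank)
    foot = ankle + anthro.foot_length * _unit(theta_foot)
    return {
        "hip": hip,
        "knee": knee,
        "ankle": ankle,
        "foot": foot,
        "thigh_com": hip + 0.5 * anthro.thigh_length * _unit(theta_thigh),
        "shank_com": knee + 0.5 * anthro.shank_length * _unit(theta_shank),
        "theta_thigh": theta_thigh,
        "theta_shank": theta_shank,
        "theta_foot": theta_foot,
    }


def _grad(arr: np.ndarray, dt: float, order: int = 1) -> np.ndarray:
    out = np.gradient(arr, dt, axis=0)
    return out if order == 1 else np.gradient(out, dt, axis=0)


def _cross_z(r: np.ndarray, f: np.ndarray) -> np.ndarray:
    return r[:, 0] * f[:, 1] - r[:, 1] * f[:, 0]


# --------------------------------------------------------------------------
# inverse dynamics
# --------------------------------------------------------------------------


@dataclass
class InverseDynamicsResult:
    """Per-leg net joint moments (flexion-positive), forces, and GRFs."""

    t: np.ndarray
    com: np.ndarray
    com_acc: np.ndarray
    grf: dict  # grf[leg] -> (n, 2) N
    leg_load: dict  # |grf| / body weight
    net_moment: dict  # net_moment[leg][joint] -> array, flexion-positive
    knee_force: dict  # intersegmental knee force magnitude, N
    foot_pos: dict  # (n, 2) sagittal foot point
    foot_clearance: dict
    grf_total: np.ndarray


def inverse_dynamics(
    kin: Kinematics,
    anthro: Anthropometry,
    scenario: ScenarioConfig,
    contact_width: float = 0.005,
) -> InverseDynamicsResult:
    """Planar Newton-Euler recursion for both legs with GRF sharing.

    The total ground reaction force is whatever closes the whole-body
    equation of motion, ``m a_com = F_grf + m g``; it is split between the
    feet by a logistic weight on each foot's ground clearance (width
    ``contact_width``), which is smooth in the kinematics -- a property the
    optimizers rely on.
    """
    dt = kin.dt
    g_vec = np.array([0.0, -scenario.gravity])
    geo = {leg: _leg_geometry(kin, anthro, leg) for leg in LEGS}

    # whole-body CoM from all segment CoMs (trunk rides above the pelvis)
    trunk_com = kin.pelvis_pos + np.array([0.0, anthro.trunk_com_height])
    m_tot = anthro.total_mass
    com = anthro.trunk_mass * trunk_com
    for leg in LEGS:
        com = com + (
            anthro.thigh_mass * geo[leg]["thigh_com"]
            + anthro.shank_mass * geo[leg]["shank_com"]
            + anthro.foot_mass * geo[leg]["foot"]
        )
    com /= m_tot
    com_acc = _grad(com, dt, order=2)

    grf_total = m_tot * (com_acc - g_vec)

    # contact sharing by foot clearance above the (possibly sloped) ground
    grade = scenario.ground_grade
    clearance = {}
    weight = {}
    for leg in LEGS:
        foot = geo[leg]["foot"]
        clearance[leg] = foot[:, 1] - grade * foot[:, 0]
        weight[leg] = expit(-clearance[leg] / contact_width)
    wsum = weight["right"] + weight["left"]
    wsum = np.where(wsum < 1e-12, 1.0, wsum)

    grf = {}
    leg_load = {}
    bw = m_tot * scenario.gravity if scenario.gravity > 0 else np.inf
    for leg in LEGS:
        share = weight[leg] / wsum
        grf[leg] = share[:, None] * grf_total
        leg_load[leg] = np.linalg.norm(grf[leg], axis=1) / bw

    net_moment: dict = {}
    knee_force: dict = {}
    I_thigh = anthro.thigh_mass * anthro.thigh_length**2 / 12.0
    I_shank = anthro.shank_mass * anthro.shank_length**2 / 12.0

    for leg in LEGS:
        g = geo[leg]
        a_foot = _grad(g["foot"], dt, order=2)
        a_shank = _grad(g["shank_com"], dt, order=2)
        a_thigh = _grad(g["thigh_com"], dt, order=2)
        alpha_shank = _grad(g["theta_shank"], dt, order=2)
        alpha_thigh = _grad(g["theta_thigh"], dt, order=2)

        # foot: point mass, GRF applied at the foot point
        f_ankle = anthro.foot_mass * (a_foot - g_vec) - grf[leg]
        m_ankle = -_cross_z(g["ankle"] - g["foot"], f_ankle)

        # shank: rod between knee and ankle
        f_knee = anthro.shank_mass * (a_shank - g_vec) + f_ankle
        m_knee = (
            I_shank * alpha_shank
            + m_ankle
            - _cross_z(g["knee"] - g["shank_com"], f_knee)
            + _cross_z(g["ankle"] - g["shank_com"], f_ankle)
        )

        # thigh: rod between hip and knee
        f_hip = anthro.thigh_mass * (a_thigh - g_vec) + f_knee
        m_hip = (
            I_thigh * alpha_thigh
            + m_knee
            - _cross_z(g["hip"] - g["thigh_com"], f_hip)
            + _cross_z(g["knee"] - g["thigh_com"], f_knee)
        )

        # convert z-couples to flexion-positive joint moments:
        # hip flexion advances theta_thigh (+z), knee flexion retracts the
        # shank (-z on theta_shank), dorsiflexion advances theta_foot (+z)
        net_moment[leg] = {
            "hip": m_hip,
            "knee": -m_knee,
            "ankle": m_ankle,
        }
        knee_force[leg] = np.linalg.norm(f_knee, axis=1)

    return InverseDynamicsResult(
        t=kin.t,
        com=com,
        com_acc=com_acc,
        grf=grf,
        leg_load=leg_load,
        net_moment=net_moment,
        knee_force=knee_force,
        foot_pos={leg: geo[leg]["foot"] for leg in LEGS},
        foot_clearance=clearance,
        grf_total=grf_total,
    )


# --------------------------------------------------------------------------
# scalar metric building blocks
# --------------------------------------------------------------------------


def knee_load(
    knee_force: np.ndarray | float,
    bio_knee_moment: np.ndarray | float,
    r_eff: float,
    body_weight: float,
) -> np.ndarray | float:
    """Normalized biological knee load.

    Intersegmental force plus a muscle-compression term |moment| / r_eff,
    divided by body weight.  The moment term makes the proxy sensitive to
    the damper offloading the biological moment.
    """
    if r_eff <= 0:
        raise ValueError("r_eff must be > 0")
    if body_weight <= 0:
        raise ValueError("body_weight must be > 0")
    return (np.abs(knee_force) + np.abs(bio_knee_moment) / r_eff) / body_weight


def metabolic_power(
    joint_powers: Sequence[np.ndarray],
    alpha_pos: float = 4.0,
    alpha_neg: float = 0.8,
    basal: float = 90.0,
) -> np.ndarray:
    """Whole-body metabolic power proxy from biological joint powers.

    ``basal + sum_j [alpha_pos * P_j^+ + alpha_neg * P_j^-]`` -- positive
    and negative mechanical work weighted by inverse muscular
    efficiencies.  Never falls below ``basal``.
    """
    if alpha_pos <= 0 or alpha_neg < 0:
        raise ValueError("alpha_pos must be > 0 and alpha_neg >= 0")
    powers = [np.asarray(p, dtype=float) for p in joint_powers]
    total = np.zeros_like(powers[0]) if powers else 0.0
    for p in powers:
        total = total + alpha_pos * np.maximum(p, 0.0) + alpha_neg * np.maximum(-p, 0.0)
    return basal + total


# --------------------------------------------------------------------------
# simulation pipeline
# --------------------------------------------------------------------------


@dataclass
class SimResult:
    """Everything one evaluation of the gait model produces."""

    t: np.ndarray
    dt: float
    stride_period: float
    body_weight: float
    total_mass: float
    angles: dict
    omegas: dict
    net_moment: dict
    bio_moment: dict
    exo_torque: dict
    joint_power: dict  # biological joint powers, W
    grf: dict
    leg_load: dict
    knee_force: dict  # intersegmental knee force magnitude, N, per leg
    knee_load: dict  # body-weight fraction, per leg
    phase_labels: dict  # phase_labels[leg] -> list[GaitPhase]
    strides: dict  # strides[leg] -> list[(i0, i1)] (may be empty)
    metabolic_series: np.ndarray
    mean_speed: float
    distance: float
    metabolic_energy: float
    cost_of_transport: float
    design: DesignParams | None
    valid: bool
    invalid_reasons: list = field(default_factory=list)

    def engaged_mask(self, leg: str) -> np.ndarray:
        if self.design is None:
            return np.zeros(len(self.t), dtype=bool)
        pattern = self.design.clutch_pattern
        return np.array([p in pattern for p in self.phase_labels[leg]])

    def scalars(self) -> dict:
        return {
            "mean_speed": self.mean_speed,
            "distance": self.distance,
            "metabolic_energy": self.metabolic_energy,
            "cost_of_transport": self.cost_of_transport,
            "valid": self.valid,
            "invalid_reasons": list(self.invalid_reasons),
            "design_c": None if self.design is None else self.design.damping_coefficient,
            "design_pattern": None if self.design is None else self.design.label(),
        }

    def to_frame(self) -> pd.DataFrame:
        cols = {"t": self.t}
        for leg in LEGS:
            s = leg[0].upper()
            cols[f"knee_angle_{s}"] = self.angles[leg]["knee"]
            cols[f"knee_omega_{s}"] = self.omegas[leg]["knee"]
            cols[f"net_knee_moment_{s}"] = self.net_moment[leg]["knee"]
            cols[f"bio_knee_moment_{s}"] = self.bio_moment[leg]["knee"]
            cols[f"exo_torque_{s}"] = self.exo_torque[leg]
            cols[f"knee_power_{s}"] = self.joint_power[leg]["knee"]
            cols[f"grf_x_{s}"] = self.grf[leg][:, 0]
            cols[f"grf_y_{s}"] = self.grf[leg][:, 1]
            cols[f"leg_load_{s}"] = self.leg_load[leg]
            cols[f"knee_load_{s}"] = self.knee_load[leg]
            cols[f"phase_{s}"] = [p.value for p in self.phase_labels[leg]]
        cols["metabolic_power"] = self.metabolic_series
        return pd.DataFrame(cols)

    def save(self, csv_path, json_path=None) -> None:
        self.to_frame().to_csv(csv_path, index=False)
        if json_path is not None:
            with open(json_path, "w") as fh:
                json.dump(self.scalars(), fh, indent=2)


KNEE_ANGLE_LIMITS = (0.0, 2.5)  # rad; violations flag the result invalid
DEFAULT_R_EFF = 0.04  # m, effective extensor moment arm for the load proxy


def simulate(
    design: DesignParams | None,
    theta: ControllerTheta,
    scenario: ScenarioConfig,
    anthro: Anthropometry,
    thresholds: PhaseThresholds | None = None,
    r_eff: float = DEFAULT_R_EFF,
    alpha_pos: float = 4.0,
    alpha_neg: float = 0.8,
    basal_per_kg: float = 1.2,
) -> SimResult:
    """Full pipeline: kinematics -> dynamics -> phases -> device -> metrics.

    ``design=None`` (or c=0) is the device-free baseline.  The stance load
    threshold used for phase segmentation comes from ``theta``, mirroring
    its role as an optimized controller parameter.
    """
    kin = generate_kinematics(theta, scenario)
    idr = inverse_dynamics(kin, anthro, scenario)

    if thresholds is None:
        thresholds = PhaseThresholds()
    stance_thr = float(np.clip(theta.stance_load_threshold, 1e-3, 2.0))
    thresholds = replace(
        thresholds,
        stance_load_threshold=stance_thr,
        swing_load_threshold=min(thresholds.swing_load_threshold, stance_thr),
    )

    # phase labeling from foot position (CoM-relative) and normalized loads
    phase_labels = {}
    for leg in LEGS:
        other = "left" if leg == "right" else "right"
        rel_x = idr.foot_pos[leg][:, 0] - idr.com[:, 0]
        states = [
            LegState(rel_x[i], idr.leg_load[leg][i], idr.leg_load[other][i])
            for i in range(len(kin.t))
        ]
        phase_labels[leg] = label_phases(states, thresholds)

    strides = {}
    invalid_reasons = []
    for leg in LEGS:
        try:
            strides[leg] = detect_strides(phase_labels[leg])
        except NoStrideError:
            strides[leg] = []
            invalid_reasons.append(f"no_strides_{leg}")

    # device torque and the net/biological moment split
    exo_torque = {}
    bio_moment = {}
    joint_power = {}
    for leg in LEGS:
        omega_knee = kin.omegas[leg]["knee"]
        if design is None:
            tau = np.zeros_like(omega_knee)
        else:
            engaged = np.array(
                [p in design.clutch_pattern for p in phase_labels[leg]]
            )
            tau = damper_torque(design.damping_coefficient, omega_knee, engaged)
        exo_torque[leg] = tau
        bio_moment[leg] = {
            j: idr.net_moment[leg][j].copy() for j in ("hip", "ankle")
        }
        bio_moment[leg]["knee"] = idr.net_moment[leg]["knee"] - tau
        joint_power[leg] = {
            j: bio_moment[leg][j] * kin.omegas[leg][j] for j in _JOINTS
        }

    metabolic_series = metabolic_power(
        [joint_power[leg][j] for leg in LEGS for j in _JOINTS],
        alpha_pos=alpha_pos,
        alpha_neg=alpha_neg,
        basal=basal_per_kg * anthro.total_mass,
    )
    metabolic_energy = float(np.trapezoid(metabolic_series, dx=scenario.dt))

    distance = float(theta.speed * scenario.duration)
    mean_speed = distance / scenario.duration

    knee_load_series = {
        leg: knee_load(
            idr.knee_force[leg],
            bio_moment[leg]["knee"],
            r_eff,
            anthro.body_weight,
        )
        for leg in LEGS
    }

    # validity screening
    if abs(mean_speed - scenario.target_speed) > scenario.speed_tolerance:
        invalid_reasons.append("speed_off_target")
    if np.any(idr.grf_total[:, 1] < -1e-9):
        invalid_reasons.append("negative_vertical_grf")
    for leg in LEGS:
        knee = kin.angles[leg]["knee"]
        if knee.min() < KNEE_ANGLE_LIMITS[0] - 1e-9 or knee.max() > KNEE_ANGLE_LIMITS[1]:
            invalid_reasons.append(f"knee_limit_{leg}")
            break

    return SimResult(
        t=kin.t,
        dt=scenario.dt,
        stride_period=theta.stride_period,
        body_weight=anthro.body_weight,
        total_mass=anthro.total_mass,
        angles=kin.angles,
        omegas=kin.omegas,
        net_moment=idr.net_moment,
        bio_moment=bio_moment,
        exo_torque=exo_torque,
        joint_power=joint_power,
        grf=idr.grf,
        leg_load=idr.leg_load,
        knee_force=idr.knee_force,
        knee_load=knee_load_series,
        phase_labels=phase_labels,
        strides=strides,
        metabolic_series=metabolic_series,
        mean_speed=mean_speed,
        distance=distance,
        metabolic_energy=metabolic_energy,
        cost_of_transport=metabolic_energy / distance,
        design=design,
        valid=not invalid_reasons,
        invalid_reasons=invalid_reasons,
    )
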