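"""Synthetic motion trajectories and IMU readings with known ground truth.

The motion model is purely kinematic: joint-angle and position profiles
are raised-cosine ramps between postures, which are C1-smooth so the
derived gyroscope and accelerometer signals are continuous.  Legs follow
prescribed hip and ankle paths through planar two-link inverse
kinematics, so foot placement, whole-body translation and segment
orientations are mutually consistent.  Supported tasks:

* ``calibration`` — quiet stance, forward lean, partial squat;
* ``swap`` — chair-to-chair transfer: rise, step towards the second
  chair, 90 degree turn, sit down;
* ``tug`` — rise, walk out, 180 degree turn, walk back, 180 degree
  turn, sit down;
* ``walk`` — stance, n steps, stance (plain walking, shuffling when the
  swing height is zero).

``imu_from_trajectory`` inverts the sensing model (gravity reaction +
linear acceleration in the sensor frame, angular velocity in the sensor
frame, optional magnetometer), with configurable noise, gyro bias and
mounting misalignment, producing the package's own input format.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Tuple

import numpy as np

from . import quat
from .errors import InputError, MappingError
from .io_model import default_body_model
from .kinematics import compute_com, forward_kinematics
from .types import GRAVITY, BodyModel, ImuSeries, PostureSeries, SessionRecord

DEG = np.pi / 180.0


def _ramp(u):
    """Raised-cosine 0 -> 1 with zero end-point velocity."""
    return 0.5 - 0.5 * np.cos(np.pi * np.clip(u, 0.0, 1.0))


def _bump(u):
    """Raised-cosine 0 -> 1 -> 0."""
    return 0.5 - 0.5 * np.cos(2.0 * np.pi * np.clip(u, 0.0, 1.0))


def _ramp_ext(u):
    """0 -> 1 with a quartically flat approach to 1.

    Used for motion that ends at full leg extension: the knee angle goes
    like the square root of the remaining hip drop, so the approach must
    be extra flat for the knee rate to vanish at the boundary.
    """
    return 1.0 - (1.0 - _ramp(u)) ** 2


def _ramp_flex(u):
    """0 -> 1 with a quartically flat departure from 0 (leaving full extension)."""
    return _ramp(u) ** 2


@dataclass
class MotionParams:
    """Ground-truth motion parameters for one simulated recording."""

    task: str = "swap"
    rate_hz: float = 100.0
    lead_in_s: float = 1.0
    tail_s: float = 1.0
    # sit-to-stand / stand-to-sit
    raise_duration_s: float = 1.4
    sit_duration_s: float = 1.5
    peak_trunk_lean_deg: float = 30.0
    pelvis_lean_ratio: float = 0.6
    peak_lateral_sway_deg: float = 3.0
    angular_speed_scale: float = 1.0   # >1 compresses the trunk-lean bump in time
    # locomotion
    step_length_m: float = 0.5
    step_duration_s: float = 0.7
    swing_height_m: float = 0.05
    chair_distance_m: float = 1.0      # SWAP chair separation
    walk_distance_m: float = 3.0       # TUG walkway / plain-walk distance
    turn_angle_deg: float = 90.0       # SWAP turn (TUG turns are 180 by definition)
    turn_duration_s: float = 1.5
    # calibration movements
    stance_s: float = 2.0
    lean_s: float = 2.0
    squat_s: float = 2.5
    lean_deg: float = 25.0
    squat_depth_m: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("rate_hz", "lead_in_s", "tail_s", "raise_duration_s", "sit_duration_s",
                     "step_duration_s", "turn_duration_s", "stance_s", "lean_s", "squat_s"):
            if getattr(self, name) <= 0:
                raise InputError(f"{name} must be > 0")
        for name in ("peak_trunk_lean_deg", "peak_lateral_sway_deg", "lean_deg"):
            v = getattr(self, name)
            if not 0.0 <= v <= 90.0:
                raise InputError(f"{name} must lie in [0, 90] deg")
        if min(self.step_length_m, self.walk_distance_m, self.chair_distance_m) <= 0:
            raise InputError("step and walk distances must be > 0")


@dataclass
class SensorNoise:
    """Per-sensor measurement imperfections."""

    accel_sigma: float = 0.0        # m/s^2
    gyro_sigma: float = 0.0         # deg/s
    gyro_bias: float = 0.0          # SD of a constant per-sensor bias, deg/s
    misalignment_deg: float = 0.0   # max mounting misalignment angle

    def __post_init__(self) -> None:
        if min(self.accel_sigma, self.gyro_sigma, self.gyro_bias,
               self.misalignment_deg) < 0:
            raise InputError("noise magnitudes must be >= 0")


#: Default per-class motion-parameter distributions (mean, SD) for cohorts.
#: Fallers are slower, sway more laterally, and move with lower angular
#: speeds than non-fallers.
NONFALLER_DIST = {
    "raise_duration_s": (1.3, 0.20),
    "sit_duration_s": (1.4, 0.20),
    "turn_duration_s": (1.4, 0.15),
    "step_duration_s": (0.70, 0.06),
    "peak_trunk_lean_deg": (30.0, 4.0),
    "peak_lateral_sway_deg": (3.0, 1.0),
    "angular_speed_scale": (1.0, 0.10),
}
FALLER_DIST = {
    "raise_duration_s": (1.9, 0.20),
    "sit_duration_s": (2.0, 0.20),
    "turn_duration_s": (1.9, 0.15),
    "step_duration_s": (0.88, 0.06),
    "peak_trunk_lean_deg": (38.0, 4.0),
    "peak_lateral_sway_deg": (6.0, 1.0),
    "angular_speed_scale": (0.75, 0.10),
}


@dataclass
class CohortParams:
    """Labelled-cohort generation settings (study shape: 8 fallers, 32 non-fallers)."""

    n_fallers: int = 8
    n_nonfallers: int = 32
    rate_hz: float = 50.0
    noise: SensorNoise = field(default_factory=lambda: SensorNoise(
        accel_sigma=0.05, gyro_sigma=0.2, gyro_bias=0.1, misalignment_deg=10.0))
    faller_dist: dict = field(default_factory=lambda: dict(FALLER_DIST))
    nonfaller_dist: dict = field(default_factory=lambda: dict(NONFALLER_DIST))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fallers < 0 or self.n_nonfallers < 0:
            raise InputError("cohort sizes must be >= 0")


# ---------------------------------------------------------------------------
# trajectory construction


class _Geometry:
    def __init__(self, model: BodyModel):
        self.model = model
        self.lt = model["thigh_l"].length
        self.ls = model["shank_l"].length
        self.hw = abs(float(model["thigh_l"].attach_offset[1]))
        self.z_stand = self.lt + self.ls  # straight legs (IK is regular at full extension)
        self.z_seat = self.ls

    def z_walk(self, step: float) -> float:
        reach = 0.99 * (self.lt + self.ls)
        return float(np.sqrt(max(reach ** 2 - (1.1 * step) ** 2,
                                 (0.5 * (self.lt + self.ls)) ** 2)))


class _Channels:
    """Per-frame scalar/vector channels filled phase by phase.

    Durations are snapped to the sample grid so every phase boundary
    falls exactly on a sample; the returned ground-truth event times are
    these snapped boundaries.
    """

    def __init__(self, durations, rate):
        self.rate = rate
        snapped = [max(1, int(round(d * rate))) / rate for d in durations]
        self.edges = np.concatenate([[0.0], np.cumsum(snapped)])
        self.n = int(round(self.edges[-1] * rate)) + 1
        self.t = np.arange(self.n) / rate
        self.yaw = np.zeros(self.n)
        self.trunk_pitch = np.zeros(self.n)
        self.pelvis_pitch = np.zeros(self.n)
        self.lat = np.zeros(self.n)
        self.hip = np.zeros((self.n, 3))
        self.ankle_l = np.zeros((self.n, 3))
        self.ankle_r = np.zeros((self.n, 3))

    def phase(self, k: int):
        """(slice, u in [0,1]) for phase k; boundary samples are shared."""
        i0 = int(round(self.edges[k] * self.rate))
        i1 = int(round(self.edges[k + 1] * self.rate))
        sl = slice(i0, i1 + 1)
        dur = self.edges[k + 1] - self.edges[k]
        u = (self.t[sl] - self.edges[k]) / dur
        return sl, np.clip(u, 0.0, 1.0)


def _heading(yaw: float) -> np.ndarray:
    return np.array([np.cos(yaw), np.sin(yaw), 0.0])


def _seated_pose(ch: _Channels, sl, g: _Geometry, yaw: float, ank_l, ank_r):
    u2 = _heading(yaw)
    center = 0.5 * (ank_l + ank_r)
    ch.yaw[sl] = yaw
    ch.ankle_l[sl] = ank_l
    ch.ankle_r[sl] = ank_r
    ch.hip[sl] = center - u2 * g.lt + np.array([0, 0, g.z_seat])


def _fill_raise(ch: _Channels, k: int, g: _Geometry, p: MotionParams, yaw: float,
                direction: int = 1):
    """Sit-to-stand (direction=+1) or stand-to-sit (direction=-1)."""
    sl, u = ch.phase(k)
    u2 = _heading(yaw)
    r = _ramp_ext(u) if direction > 0 else 1.0 - _ramp_flex(u)
    ank_c = 0.5 * (ch.ankle_l[sl.start] + ch.ankle_r[sl.start])
    ch.yaw[sl] = yaw
    ch.ankle_l[sl] = ch.ankle_l[sl.start]
    ch.ankle_r[sl] = ch.ankle_r[sl.start]
    ch.hip[sl] = (ank_c - u2 * g.lt * (1.0 - r)[:, None]
                  + np.array([0, 0, 1.0]) * (g.z_seat + (g.z_stand - g.z_seat) * r)[:, None])
    f = np.clip(1.0 / max(p.angular_speed_scale, 1e-3), 0.3, 1.0)
    lean = p.peak_trunk_lean_deg * DEG * _bump(u / f)
    ch.trunk_pitch[sl] = lean
    ch.pelvis_pitch[sl] = p.pelvis_lean_ratio * lean
    ch.lat[sl] = p.peak_lateral_sway_deg * DEG * _bump(u)


def _fill_walk(ch: _Channels, k: int, g: _Geometry, p: MotionParams, yaw: float,
               distance: float, swing_height: float):
    """n alternating steps advancing the mid-foot point by ``distance``."""
    sl, u = ch.phase(k)
    u2 = _heading(yaw)
    n_steps = max(2, int(round(distance / p.step_length_m)))
    s_eff = distance / n_steps
    start_l = ch.ankle_l[sl.start].copy()
    start_r = ch.ankle_r[sl.start].copy()
    z0 = ch.hip[sl.start, 2]
    zw = g.z_walk(s_eff)
    ch.yaw[sl] = yaw
    pos = {"l": start_l.copy(), "r": start_r.copy()}
    origin_adv = 0.5 * float((start_l + start_r) @ u2)
    al = np.tile(start_l, (len(u), 1))
    ar = np.tile(start_r, (len(u), 1))
    feet = {"l": al, "r": ar}
    for step in range(n_steps):
        foot = "r" if step % 2 == 0 else "l"
        v = np.clip(u * n_steps - step, 0.0, 1.0)
        target_adv = origin_adv + min((step + 2) * s_eff, n_steps * s_eff)
        cur_adv = float(pos[foot] @ u2)
        advance = max(target_adv - cur_adv, 0.0)
        traj = pos[foot][None, :] + u2[None, :] * (advance * _ramp(v))[:, None]
        traj = traj + np.array([0, 0, 1.0])[None, :] * (swing_height * _bump(v))[:, None]
        active = v > 0.0
        feet[foot][active] = traj[active]
        pos[foot] = pos[foot] + u2 * advance
    ch.ankle_l[sl] = al
    ch.ankle_r[sl] = ar
    mid = 0.5 * (al + ar)
    # hip above the mid-foot point; dip to the reachable walking height
    k1 = 1.0 / n_steps
    z = (z0 + (zw - z0) * _ramp_flex(u / k1)
         + (g.z_stand - zw) * _ramp_ext((u - (1 - k1)) / k1))
    ch.hip[sl, :2] = mid[:, :2]
    ch.hip[sl, 2] = z


def _fill_turn(ch: _Channels, k: int, g: _Geometry, p: MotionParams,
               yaw0: float, angle: float):
    sl, u = ch.phase(k)
    psi = yaw0 + angle * _ramp(u)
    center = 0.5 * (ch.ankle_l[sl.start] + ch.ankle_r[sl.start])
    off = np.stack([-np.sin(psi) * g.hw, np.cos(psi) * g.hw, np.zeros_like(psi)], axis=1)
    ch.yaw[sl] = psi
    ch.ankle_l[sl] = center + off
    ch.ankle_r[sl] = center - off
    ch.hip[sl, :2] = center[:2]
    ch.hip[sl, 2] = ch.hip[sl.start, 2]


def _fill_hold(ch: _Channels, k: int):
    sl, _ = ch.phase(k)
    for arr in (ch.yaw, ch.trunk_pitch, ch.pelvis_pitch, ch.lat):
        arr[sl] = arr[sl.start]
    for arr in (ch.hip, ch.ankle_l, ch.ankle_r):
        arr[sl] = arr[sl.start]


def _fill_sit(ch: _Channels, k: int, g: _Geometry, p: MotionParams, yaw: float):
    _fill_raise(ch, k, g, p, yaw, direction=-1)


def _leg_ik(hip: np.ndarray, ankle: np.ndarray, yaw: np.ndarray,
            lt: float, ls: float) -> Tuple[np.ndarray, np.ndarray]:
    """Planar two-link IK: hip flexion alpha and shank tilt beta (rad)."""
    d = ankle - hip
    dx = np.cos(yaw) * d[:, 0] + np.sin(yaw) * d[:, 1]
    dz = d[:, 2]
    r = np.minimum(np.hypot(dx, dz), lt + ls)
    cosk = np.clip((r ** 2 - lt ** 2 - ls ** 2) / (2 * lt * ls), -1.0, 1.0)
    knee = np.arccos(cosk)
    phi = np.arctan2(dx, -dz)
    alpha = phi + np.arcsin(np.clip(ls * np.sin(knee) / np.maximum(r, 1e-9), -1.0, 1.0))
    return alpha, alpha - knee


def _assemble(model: BodyModel, ch: _Channels) -> PostureSeries:
    g = _Geometry(model)
    q_pelvis = quat.from_euler_zyx(ch.yaw, ch.pelvis_pitch, np.zeros_like(ch.yaw))
    q_trunk = quat.from_euler_zyx(ch.yaw, ch.trunk_pitch, ch.lat)
    seg_q = {"pelvis": q_pelvis, "trunk": q_trunk}
    for side, sign in (("l", 1.0), ("r", -1.0)):
        hip_j = ch.hip + quat.rotate(q_pelvis, np.array([0.0, sign * g.hw, 0.0]))
        ankle = ch.ankle_l if side == "l" else ch.ankle_r
        alpha, beta = _leg_ik(hip_j, ankle, ch.yaw, g.lt, g.ls)
        zeros = np.zeros_like(alpha)
        seg_q[f"thigh_{side}"] = quat.from_euler_zyx(ch.yaw, -alpha, zeros)
        seg_q[f"shank_{side}"] = quat.from_euler_zyx(ch.yaw, -beta, zeros)
    joints = forward_kinematics(seg_q, model, ch.n)
    world_joints = {name: {kk: vv + ch.hip for kk, vv in jj.items()}
                    for name, jj in joints.items()}
    posture = PostureSeries(model=model, t=ch.t, seg_q=seg_q,
                            root_pos=ch.hip, joints=world_joints)
    posture.com = compute_com(posture, model)
    return posture


def simulate_trajectory(params: MotionParams,
                        model: Optional[BodyModel] = None
                        ) -> Tuple[PostureSeries, Dict[str, float]]:
    """Ground-truth posture series plus exact phase-boundary times."""
    model = model or default_body_model()
    g = _Geometry(model)
    p = params
    ank_l0 = np.array([0.0, g.hw, 0.0])
    ank_r0 = np.array([0.0, -g.hw, 0.0])

    if p.task == "swap":
        n_steps = max(2, int(round(p.chair_distance_m / p.step_length_m)))
        durations = [p.lead_in_s, p.raise_duration_s, n_steps * p.step_duration_s,
                     p.turn_duration_s, p.sit_duration_s, p.tail_s]
        ch = _Channels(durations, p.rate_hz)
        sl, _ = ch.phase(0)
        _seated_pose(ch, sl, g, 0.0, ank_l0, ank_r0)
        _fill_raise(ch, 1, g, p, 0.0)
        _fill_walk(ch, 2, g, p, 0.0, p.chair_distance_m, p.swing_height_m)
        _fill_turn(ch, 3, g, p, 0.0, p.turn_angle_deg * DEG)
        _fill_sit(ch, 4, g, p, p.turn_angle_deg * DEG)
        _fill_hold(ch, 5)
        e = ch.edges
        events = {"raise_start": e[1], "raise_end": e[2],
                  "sit_start": e[4], "sit_end": e[5]}
    elif p.task == "tug":
        walk_d = p.walk_distance_m
        n_steps = max(2, int(round(walk_d / p.step_length_m)))
        walk_s = n_steps * p.step_duration_s
        durations = [p.lead_in_s, p.raise_duration_s, walk_s, p.turn_duration_s,
                     walk_s, p.turn_duration_s, p.sit_duration_s, p.tail_s]
        ch = _Channels(durations, p.rate_hz)
        sl, _ = ch.phase(0)
        _seated_pose(ch, sl, g, 0.0, ank_l0, ank_r0)
        _fill_raise(ch, 1, g, p, 0.0)
        _fill_walk(ch, 2, g, p, 0.0, walk_d, p.swing_height_m)
        _fill_turn(ch, 3, g, p, 0.0, np.pi)
        _fill_walk(ch, 4, g, p, np.pi, walk_d, p.swing_height_m)
        _fill_turn(ch, 5, g, p, np.pi, np.pi)
        _fill_sit(ch, 6, g, p, 2.0 * np.pi)
        _fill_hold(ch, 7)
        e = ch.edges
        events = {"raise_start": e[1], "raise_end": e[2],
                  "turn1_start": e[3], "turn1_end": e[4],
                  "turn2_start": e[5], "sit_start": e[6], "sit_end": e[7]}
    elif p.task == "calibration":
        durations = [p.stance_s, p.lean_s, p.squat_s, 0.5]
        ch = _Channels(durations, p.rate_hz)
        sl, _ = ch.phase(0)
        ch.ankle_l[sl] = ank_l0
        ch.ankle_r[sl] = ank_r0
        ch.hip[sl] = np.array([0.0, 0.0, g.z_stand])
        sl, u = ch.phase(1)  # forward lean
        _fill_hold(ch, 1)
        lean = p.lean_deg * DEG * _bump(u)
        ch.trunk_pitch[sl] = lean
        ch.pelvis_pitch[sl] = 0.8 * lean
        sl, u = ch.phase(2)  # partial squat, knees forward
        _fill_hold(ch, 2)
        # squared bump: quartically flat at both ends, where the legs reach
        # full extension and the knee angle is a square root of the hip drop
        ch.hip[sl, 2] = g.z_stand - p.squat_depth_m * _bump(u) ** 2
        lean = 10.0 * DEG * _bump(u)
        ch.trunk_pitch[sl] = lean
        ch.pelvis_pitch[sl] = 0.8 * lean
        _fill_hold(ch, 3)
        e = ch.edges
        events = {"stance_start": e[0], "stance_end": e[1],
                  "movement_start": e[1], "movement_end": e[3]}
    elif p.task == "walk":
        n_steps = max(2, int(round(p.walk_distance_m / p.step_length_m)))
        durations = [p.lead_in_s, n_steps * p.step_duration_s, p.tail_s]
        ch = _Channels(durations, p.rate_hz)
        sl, _ = ch.phase(0)
        ch.ankle_l[sl] = ank_l0
        ch.ankle_r[sl] = ank_r0
        ch.hip[sl] = np.array([0.0, 0.0, g.z_stand])
        _fill_walk(ch, 1, g, p, 0.0, p.walk_distance_m, p.swing_height_m)
        _fill_hold(ch, 2)
        e = ch.edges
        events = {"walk_start": e[1], "walk_end": e[2]}
    elif p.task == "stance":
        durations = [p.lead_in_s + p.stance_s + p.tail_s]
        ch = _Channels(durations, p.rate_hz)
        sl, _ = ch.phase(0)
        ch.ankle_l[sl] = ank_l0
        ch.ankle_r[sl] = ank_r0
        ch.hip[sl] = np.array([0.0, 0.0, g.z_stand])
        events = {}
    else:
        raise InputError(f"unknown task {params.task!r}")
    return _assemble(model, ch), events


# ---------------------------------------------------------------------------
# IMU synthesis


def draw_misalignments(model: BodyModel, max_deg: float,
                       rng: np.random.Generator) -> Dict[str, np.ndarray]:
    """Random mounting rotation (segment<-sensor) per sensor, up to max_deg."""
    out = {}
    for seg in model.segments:
        if seg.sensor_id is None:
            continue
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        angle = rng.uniform(0.0, max_deg) * DEG
        out[seg.sensor_id] = quat.from_axis_angle(axis, angle)
    return out


def imu_from_trajectory(posture: PostureSeries, model: Optional[BodyModel] = None,
                        noise: Optional[SensorNoise] = None,
                        misalignments: Optional[Dict[str, np.ndarray]] = None,
                        rng: Optional[np.random.Generator] = None,
                        task: str = "stance", subject_id: str = "sim",
                        with_mag: bool = False,
                        mag_field=(0.4, 0.0, -0.3)) -> SessionRecord:
    """Synthesize per-sensor IMU streams from a ground-truth posture series.

    Per sensor: gyro = segment angular velocity in the sensor frame plus
    bias and noise; accel = sensor-frame gravity reaction plus the linear
    acceleration of the sensor's attachment point; mounting misalignment
    rotates the sensor frame relative to the segment frame.
    """
    model = model or posture.model
    noise = noise or SensorNoise()
    rng = rng or np.random.default_rng(0)
    t = posture.t
    streams: Dict[str, ImuSeries] = {}
    mag_world = np.asarray(mag_field, dtype=float)
    for seg in model.segments:
        sid = seg.sensor_id
        if sid is None:
            continue
        if seg.name not in posture.seg_q:
            raise MappingError(f"segment {seg.name} missing from the posture series")
        q_seg = quat.enforce_continuity(posture.seg_q[seg.name])
        if misalignments and sid in misalignments:
            q_sw = quat.multiply(q_seg, misalignments[sid][None, :])
        else:
            q_sw = q_seg
        omega_w = quat.angular_velocity_world(t, q_sw)
        gyro = quat.rotate(quat.conjugate(q_sw), omega_w) / DEG
        # sensor sits at the segment mid-point
        prox = posture.joints[seg.name]["proximal"]
        pos = prox + quat.rotate(q_seg, seg.axis_local * seg.length * 0.5)
        acc_w = np.gradient(np.gradient(pos, t, axis=0), t, axis=0)
        acc_w[:, 2] += GRAVITY
        accel = quat.rotate(quat.conjugate(q_sw), acc_w)
        bias = rng.normal(0.0, noise.gyro_bias, size=3) if noise.gyro_bias else np.zeros(3)
        if noise.gyro_sigma:
            gyro = gyro + rng.normal(0.0, noise.gyro_sigma, size=gyro.shape)
        gyro = gyro + bias
        if noise.accel_sigma:
            accel = accel + rng.normal(0.0, noise.accel_sigma, size=accel.shape)
        mag = None
        if with_mag:
            mag = quat.rotate(quat.conjugate(q_sw), np.broadcast_to(mag_world, accel.shape))
            if noise.accel_sigma:
                mag = mag + rng.normal(0.0, 0.01, size=mag.shape)
        streams[sid] = ImuSeries(sensor_id=sid, t=t.copy(), accel=accel, gyro=gyro, mag=mag)
    return SessionRecord(subject_id=subject_id, task=task, streams=streams)


def simulate_session(params: MotionParams, model: Optional[BodyModel] = None,
                     noise: Optional[SensorNoise] = None,
                     misalignments: Optional[Dict[str, np.ndarray]] = None,
                     rng: Optional[np.random.Generator] = None,
                     subject_id: str = "sim"):
    """Convenience wrapper: trajectory + IMU synthesis.

    Returns (SessionRecord, ground-truth PostureSeries, event times).
    """
    model = model or default_body_model()
    posture, events = simulate_trajectory(params, model)
    task = "calibration_start" if params.task == "calibration" else params.task
    rec = imu_from_trajectory(posture, model, noise, misalignments, rng,
                              task=task, subject_id=subject_id)
    return rec, posture, events


# ---------------------------------------------------------------------------
# cohorts


def _draw_params(dist: dict, rng: np.random.Generator, task: str,
                 rate_hz: float) -> MotionParams:
    draws = {}
    for name, (mean, sd) in dist.items():
        lo, hi = (0.05, None)
        v = float(rng.normal(mean, sd))
        if name.endswith("_deg"):
            v = float(np.clip(v, 0.0, 90.0))
        else:
            v = max(v, lo)
        draws[name] = v
    return MotionParams(task=task, rate_hz=rate_hz, **draws)


def generate_cohort(cp: CohortParams, model: Optional[BodyModel] = None,
                    config=None) -> dict:
    """Simulate a labelled cohort and run the full pipeline per subject.

    Every subject gets two calibration recordings plus one SWAP and one
    TUG recording, all with the same mounting misalignment; features come
    from the real fusion -> calibration -> kinematics -> segmentation
    path.  Returns ``{"features": {set_name: [FeatureVector]},
    "labels": {subject_id: label}, "failed": {subject_id: reason}}``.
    """
    from .pipeline import PipelineConfig, run_subject  # local import: avoid cycle

    model = model or default_body_model()
    config = config or PipelineConfig()
    rng = np.random.default_rng(cp.seed)
    features: Dict[str, list] = {}
    labels: Dict[str, str] = {}
    failed: Dict[str, str] = {}
    plan = [("faller", i, cp.faller_dist) for i in range(cp.n_fallers)]
    plan += [("non-faller", i, cp.nonfaller_dist) for i in range(cp.n_nonfallers)]
    for label, i, dist in plan:
        subject_id = f"{label}_{i:02d}"
        mis = draw_misalignments(model, cp.noise.misalignment_deg, rng)
        sessions = {}
        base = _draw_params(dist, rng, "swap", cp.rate_hz)
        for task, rec_task in (("calibration", "calibration_start"),
                               ("swap", "swap"), ("tug", "tug"),
                               ("calibration", "calibration_end")):
            p = replace(base, task=task)
            posture, _ = simulate_trajectory(p, model)
            rec = imu_from_trajectory(posture, model, cp.noise, mis, rng,
                                      task=rec_task, subject_id=subject_id)
            rec.label = label
            sessions[rec_task] = rec
        try:
            fvs, _ = run_subject(sessions, model, config)
        except Exception as exc:  # noqa: BLE001 - cohort continues past one failure
            failed[subject_id] = f"{type(exc).__name__}: {exc}"
            continue
        labels[subject_id] = label
        for set_name, fv in fvs.items():
            features.setdefault(set_name, []).append(fv)
    return {"features": features, "labels": labels, "failed": failed}
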