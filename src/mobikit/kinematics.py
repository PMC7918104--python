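"""Rigid-body posture reconstruction, COM, walk translation, foot forces.

The body is a tree of rigid segments.  Given calibrated segment
orientations and the segment lengths, forward kinematics propagates
joint positions down the chain: a child's proximal joint coincides with
its attachment point on the parent.  Whole-body translation is not
directly measurable, so it is accumulated from the anchor-foot
assumption: a foot in ground contact is world-stationary.  When no foot
clearly leaves the ground (shuffling), the fallback picks as anchor the
foot moving backward relative to the mid-point between the feet along
the torso's front direction.

Coordinates: world right-handed, Z up, X = subject's front at the start
of the recording, positions in metres.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional

import numpy as np
from scipy.signal import butter, filtfilt

from . import quat
from .errors import AlignmentError, CapabilityError, MappingError, ModelError
from .types import GRAVITY, BodyModel, FootForces, OrientationSeries, PostureSeries


@dataclass
class KinematicsConfig:
    """Config keys ``kinematics.*``."""

    smoothing_hz: float = 5.0
    anchor_policy: str = "auto"       # auto | stance | shuffle | none
    stance_max_speed: float = 0.05    # m/s, vertical, for stance detection
    stance_max_height: float = 0.03   # m above the ground estimate


def resample_to_common_clock(series: Dict[str, OrientationSeries],
                             rate: Optional[float] = None) -> Dict[str, OrientationSeries]:
    """Slerp every series onto one uniform clock covering the shared window."""
    t0 = max(s.t[0] for s in series.values())
    t1 = min(s.t[-1] for s in series.values())
    if t1 <= t0:
        raise AlignmentError("orientation series share no common time window")
    if rate is None:
        rate = max(1.0 / float(np.median(np.diff(s.t))) for s in series.values())
    n = int(np.floor((t1 - t0) * rate)) + 1
    t_new = t0 + np.arange(n) / rate
    return {k: s.resampled(t_new) for k, s in series.items()}


def _segment_quats(series: Dict[str, OrientationSeries], model: BodyModel,
                   t: np.ndarray) -> Dict[str, np.ndarray]:
    """Per-segment orientation arrays; sensorless segments inherit the parent's."""
    seg_q: Dict[str, np.ndarray] = {}
    by_segment = {}
    sensor_map = model.sensor_map
    for sid, s in series.items():
        if sid in sensor_map:
            by_segment[sensor_map[sid]] = s.q
        elif sid in model:
            by_segment[sid] = s.q  # series keyed directly by segment name
        else:
            raise MappingError(f"series {sid!r} matches no sensor or segment in the model")
    for seg in model.topological_order():
        if seg.name in by_segment:
            seg_q[seg.name] = by_segment[seg.name]
        elif seg.parent in seg_q:
            seg_q[seg.name] = seg_q[seg.parent]
        else:
            raise MappingError(f"no orientation available for root segment {seg.name}")
    return seg_q


def forward_kinematics(seg_q: Dict[str, np.ndarray], model: BodyModel,
                       n: int) -> Dict[str, Dict[str, np.ndarray]]:
    """Joint positions relative to the root proximal joint at the origin."""
    joints: Dict[str, Dict[str, np.ndarray]] = {}
    for seg in model.topological_order():
        q = seg_q[seg.name]
        if seg.parent in (None, "ground"):
            prox = np.zeros((n, 3))
        else:
            parent_joints = joints[seg.parent]
            base = parent_joints[seg.attach]
            prox = base + quat.rotate(seg_q[seg.parent], seg.attach_offset)
        dist = prox + quat.rotate(q, seg.axis_local * seg.length)
        joints[seg.name] = {"proximal": prox, "distal": dist}
    return joints


def _feet_segments(model: BodyModel) -> List[str]:
    """Leaf segments of the legs; their distal joints are the feet."""
    leaves = [s for s in model.segments if not model.children(s.name)]
    return [s.name for s in leaves if s.descends]


def _smooth(x: np.ndarray, rate: float, cutoff_hz: float) -> np.ndarray:
    if len(x) < 15 or cutoff_hz <= 0 or cutoff_hz >= rate / 2:
        return x
    b, a = butter(2, cutoff_hz / (rate / 2))
    return filtfilt(b, a, x, axis=0)


def walk_translation(t: np.ndarray, foot_left: np.ndarray, foot_right: np.ndarray,
                     torso_front: np.ndarray,
                     cfg: Optional[KinematicsConfig] = None) -> np.ndarray:
    """Root translation from per-frame anchor-foot selection.

    Inputs are foot (ankle) trajectories *relative to the root* and the
    horizontal torso front direction per frame.  The translation T is
    accumulated so the anchor foot is world-stationary during its
    stance; T_z keeps the anchor foot on the ground plane.
    """
    cfg = cfg or KinematicsConfig()
    n = len(t)
    rate = 1.0 / float(np.median(np.diff(t)))
    fl = _smooth(foot_left, rate, 10.0)
    fr = _smooth(foot_right, rate, 10.0)
    rel_height = fl[:, 2] - fr[:, 2]
    dvel = np.gradient(fl - fr, t, axis=0)  # inter-foot relative velocity
    front = torso_front.copy()
    front[:, 2] = 0.0
    norms = np.linalg.norm(front, axis=1, keepdims=True)
    if np.any(norms < 1e-9):
        raise CapabilityError("torso front direction undefined")
    front /= norms
    feet = {"left": fl, "right": fr}
    anchor = "left"
    T = np.zeros((n, 3))
    anchors = []
    for i in range(n):
        if i > 0:
            prev = anchor
            if cfg.anchor_policy in ("auto", "stance"):
                if rel_height[i] < -cfg.stance_max_height:
                    anchor = "left"
                elif rel_height[i] > cfg.stance_max_height:
                    anchor = "right"
                elif cfg.anchor_policy == "auto":
                    anchor = _shuffle_anchor(dvel[i], front[i], prev)
            elif cfg.anchor_policy == "shuffle":
                anchor = _shuffle_anchor(dvel[i], front[i], prev)
            fa = feet[anchor]
            # continuity at anchor hand-over: the new anchor's world
            # position at frame i-1 is carried over
            T[i, :2] = T[i - 1, :2] + fa[i - 1, :2] - fa[i, :2]
        anchors.append(anchor)
    # vertical: anchor foot on the ground plane
    for i in range(n):
        T[i, 2] = -feet[anchors[i]][i, 2]
    # horizontal origin: mid-point between the feet at the first frame
    mid0 = 0.5 * (fl[0, :2] + fr[0, :2])
    T[:, :2] -= T[0, :2] + mid0
    return T


def _shuffle_anchor(dvel: np.ndarray, front: np.ndarray, prev: str) -> str:
    """Anchor = the foot moving backward relative to the mid-foot point."""
    # displacement rate of left foot relative to the mid-point, along front
    rel = 0.5 * float(dvel[:2] @ front[:2])
    eps = 0.02  # m/s dead band: keep the previous anchor when ambiguous
    if rel < -eps:
        return "left"
    if rel > eps:
        return "right"
    return prev


def reconstruct_posture(series: Dict[str, OrientationSeries], model: BodyModel,
                        anchor: str = "auto",
                        cfg: Optional[KinematicsConfig] = None,
                        rate: Optional[float] = None) -> PostureSeries:
    """Full-body posture from calibrated segment orientations.

    Joint positions follow by forward kinematics; whole-body translation
    follows the anchor policy (``none`` keeps the root at the origin).
    """
    cfg = cfg or KinematicsConfig()
    cfg.anchor_policy = anchor if anchor else cfg.anchor_policy
    series = resample_to_common_clock(series, rate=rate)
    t = next(iter(series.values())).t
    n = len(t)
    seg_q = _segment_quats(series, model, t)
    joints = forward_kinematics(seg_q, model, n)
    feet = _feet_segments(model)
    if cfg.anchor_policy == "none" or len(feet) < 2:
        # single-segment and footless models: root affixed to the ground
        root_pos = np.zeros((n, 3))
    else:
        left = [f for f in feet if f.endswith("_l")] or [feet[0]]
        right = [f for f in feet if f.endswith("_r")] or [feet[-1]]
        torso = model.root.name
        front = quat.rotate(seg_q[torso], np.array([1.0, 0.0, 0.0]))
        root_pos = walk_translation(t, joints[left[0]]["distal"],
                                    joints[right[0]]["distal"], front, cfg)
    world_joints = {name: {k: v + root_pos for k, v in j.items()}
                    for name, j in joints.items()}
    posture = PostureSeries(model=model, t=t, seg_q=seg_q, root_pos=root_pos,
                            joints=world_joints)
    posture.com = compute_com(posture, model)
    return posture


def compute_com(posture: PostureSeries, model: BodyModel) -> np.ndarray:
    """Whole-body COM: mass-fraction-weighted mean of segment COM positions.

    Fractions need not sum to 1 (arms are not modelled); the weighted sum
    is normalised by the total modelled fraction.
    """
    total = sum(s.mass_fraction for s in model.segments)
    if total <= 0:
        raise ModelError("all mass fractions are zero")
    n = len(posture.t)
    acc = np.zeros((n, 3))
    for seg in model.segments:
        prox = posture.joints[seg.name]["proximal"]
        com = prox + quat.rotate(posture.seg_q[seg.name],
                                 seg.axis_local * seg.length * seg.com_offset)
        acc += seg.mass_fraction * com
    return acc / total


def foot_forces(com: np.ndarray, model: BodyModel, posture: PostureSeries,
                cfg: Optional[KinematicsConfig] = None) -> FootForces:
    """Vertical ground-reaction force per foot.

    Total vertical force is m (g + a_com,z) with the COM acceleration
    from smoothed second differences.  In double support it is divided by
    the lever rule along the inter-foot line (inverse proportion of the
    horizontal COM distance to each foot); in single support the stance
    foot carries everything.
    """
    cfg = cfg or KinematicsConfig()
    t = posture.t
    rate = posture.rate
    feet = _feet_segments(model)
    if len(feet) < 2:
        raise CapabilityError("foot forces need both feet in the model")
    left_name = [f for f in feet if f.endswith("_l")][0]
    right_name = [f for f in feet if f.endswith("_r")][0]
    pl = posture.joints[left_name]["distal"]
    pr = posture.joints[right_name]["distal"]
    com_s = _smooth(com, rate, cfg.smoothing_hz)
    a_z = np.gradient(np.gradient(com_s[:, 2], t), t)
    total = model.total_mass * (GRAVITY + a_z)
    total = np.maximum(total, 0.0)
    ground = np.minimum(pl[:, 2], pr[:, 2])
    left_up = pl[:, 2] - ground > cfg.stance_max_height
    right_up = pr[:, 2] - ground > cfg.stance_max_height
    n = len(t)
    fl = np.zeros(n)
    fr = np.zeros(n)
    support = np.empty(n, dtype=object)
    clamped = np.zeros(n, dtype=bool)
    d = pr[:, :2] - pl[:, :2]
    d2 = np.einsum("ij,ij->i", d, d)
    s_raw = np.where(d2 > 1e-12,
                     np.einsum("ij,ij->i", com_s[:, :2] - pl[:, :2], d) / np.where(d2 > 1e-12, d2, 1.0),
                     0.5)
    s = np.clip(s_raw, 0.0, 1.0)
    for i in range(n):
        if right_up[i] and not left_up[i]:
            fl[i], fr[i], support[i] = total[i], 0.0, "left"
        elif left_up[i] and not right_up[i]:
            fl[i], fr[i], support[i] = 0.0, total[i], "right"
        else:
            fl[i] = (1.0 - s[i]) * total[i]
            fr[i] = s[i] * total[i]
            support[i] = "double"
            clamped[i] = bool(s_raw[i] < 0.0 or s_raw[i] > 1.0)
    return FootForces(t=t, left=fl, right=fr, support=support, clamped=clamped)
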