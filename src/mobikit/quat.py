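"""Quaternion helpers.

Conventions used throughout the package:

* quaternions are scalar-first ``(w, x, y, z)``, Hamilton product;
* a quaternion maps sensor/segment-frame vectors into the world frame,
  i.e. ``v_world = q * v * q^-1``;
* the world frame is right-handed with Z up; Euler angles are intrinsic
  Z-Y-X (yaw, pitch, roll), so a positive pitch tips the segment's +Z
  axis towards world +X (a forward lean).

Thin wrappers around :mod:`scipy.spatial.transform` where convenient;
hot loops use the explicit ndarray formulas below.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation, Slerp

IDENTITY = np.array([1.0, 0.0, 0.0, 0.0])


def normalize(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    return q / np.linalg.norm(q, axis=-1, keepdims=True)


def conjugate(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    out = q.copy()
    out[..., 1:] = -out[..., 1:]
    return out


def multiply(q1: np.ndarray, q2: np.ndarray) -> np.ndarray:
    """Hamilton product, broadcasting over leading axes."""
    q1 = np.asarray(q1, dtype=float)
    q2 = np.asarray(q2, dtype=float)
    w1, x1, y1, z1 = (q1[..., i] for i in range(4))
    w2, x2, y2, z2 = (q2[..., i] for i in range(4))
    return np.stack(
        [
            w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
            w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
            w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
            w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
        ],
        axis=-1,
    )


def rotate(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotate vector(s) ``v`` by quaternion(s) ``q`` (frame -> world)."""
    q = np.asarray(q, dtype=float)
    v = np.asarray(v, dtype=float)
    qv = q[..., 1:]
    t = 2.0 * np.cross(qv, v)
    return v + q[..., :1] * t + np.cross(qv, t)


def to_rotation(q: np.ndarray) -> Rotation:
    q = np.asarray(q, dtype=float)
    return Rotation.from_quat(np.roll(q, -1, axis=-1))  # -> (x,y,z,w)


def from_rotation(r: Rotation) -> np.ndarray:
    return np.roll(np.atleast_2d(r.as_quat()), 1, axis=-1).squeeze()


def from_axis_angle(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    return from_rotation(Rotation.from_rotvec(axis * angle_rad))


def from_euler_zyx(yaw: float, pitch: float, roll: float, degrees: bool = False) -> np.ndarray:
    """Intrinsic yaw-pitch-roll (Z-Y-X) to quaternion; supports arrays."""
    ang = np.stack(np.broadcast_arrays(yaw, pitch, roll), axis=-1)
    return from_rotation(Rotation.from_euler("ZYX", ang, degrees=degrees))


def to_euler_zyx(q: np.ndarray, degrees: bool = False) -> np.ndarray:
    """Quaternion to (yaw, pitch, roll), intrinsic Z-Y-X."""
    return to_rotation(q).as_euler("ZYX", degrees=degrees)


def angle_between(q1: np.ndarray, q2: np.ndarray) -> np.ndarray:
    """Geodesic angle (rad) between two orientations."""
    d = multiply(conjugate(q1), q2)
    w = np.clip(np.abs(d[..., 0]), -1.0, 1.0)
    return 2.0 * np.arccos(w)


def enforce_continuity(q: np.ndarray) -> np.ndarray:
    """Flip signs along a quaternion time series so q[i].q[i+1] >= 0."""
    q = np.array(q, dtype=float)
    for i in range(1, len(q)):
        if np.dot(q[i - 1], q[i]) < 0:
            q[i] = -q[i]
    return q


def slerp_series(t: np.ndarray, q: np.ndarray, t_new: np.ndarray) -> np.ndarray:
    """Resample a quaternion series onto a new clock via slerp."""
    sl = Slerp(t, to_rotation(enforce_continuity(q)))
    t_new = np.clip(t_new, t[0], t[-1])
    return np.atleast_2d(from_rotation(sl(t_new)))


def angular_velocity_world(t: np.ndarray, q: np.ndarray) -> np.ndarray:
    """World-frame angular velocity (rad/s) by central differences.

    omega = 2 * dq/dt * q^-1 for the frame->world convention.
    """
    q = enforce_continuity(q)
    dq = np.gradient(q, t, axis=0)
    w = 2.0 * multiply(dq, conjugate(q))
    return w[:, 1:]


def yaw_of(q: np.ndarray) -> np.ndarray:
    """Heading (rad) of the rotated +X axis projected on the ground plane."""
    x = rotate(q, np.array([1.0, 0.0, 0.0]))
    return np.arctan2(x[..., 1], x[..., 0])
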