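"""Sensor orientation estimation from raw IMU streams.

Two estimators are provided:

* ``madgwick`` — gradient-descent quaternion filter fusing gyroscope
  integration with an accelerometer (and optionally magnetometer)
  correction.  The correction gain ``beta`` (rad/s) trades gyro drift
  against distortion by linear acceleration.
* ``complementary`` — pitch/roll from the low-pass-filtered gravity
  direction measured by the accelerometer, yaw from integrated gyro.
  Accurate for stationary or quasi-stationary movement; the gravity
  estimate assumes linear accelerations average out below the cut-off.

Frame conventions: world Z up; a level, static sensor reads
``accel = (0, 0, +9.81)`` m/s^2 (the accelerometer measures the reaction
to gravity); quaternions map sensor-frame vectors to world-frame.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt

from . import quat
from .errors import FusionError
from .types import GRAVITY, ImuSample, ImuSeries, OrientationSeries

DEG = np.pi / 180.0


@dataclass
class FusionParams:
    """Tunable fusion settings (config keys ``fusion.*``)."""

    method: str = "madgwick"
    beta: float = 0.1          # Madgwick gain, rad/s
    warmup_s: float = 1.0      # initial high-gain window for fast convergence
    warmup_beta: float = 0.5
    lowpass_hz: float = 0.5    # gravity-estimate cut-off for the complementary method
    use_mag: bool = False      # magnetometer heading correction (off: unreliable indoors)
    accel_gate: float = 0.05   # skip the gravity correction when | |a|/g - 1 | exceeds this
                               # (the accelerometer is then dominated by linear acceleration)
    gyro_gate_dps: float = 20.0  # skip the gravity correction above this rotation rate:
                                 # fast movement implies linear acceleration; trust the gyro


def _tilt_from_accel(accel: np.ndarray) -> np.ndarray:
    """Initial orientation (yaw = 0) consistent with a measured gravity reaction."""
    ax, ay, az = accel
    pitch = np.arctan2(-ax, np.hypot(ay, az))
    # stabilised roll: indeterminate near pitch +-90, where az and ay both
    # vanish; bias towards roll = 0 instead of flipping to 180
    roll = np.arctan2(ay, np.sqrt(az ** 2 + 0.01 * ax ** 2) * np.sign(az + 0.1 * abs(ax)))
    return quat.from_euler_zyx(0.0, pitch, roll)


def _gravity_objective(q: np.ndarray, a_hat: np.ndarray):
    """Madgwick gravity objective f and gradient J^T f (batched over leading axes)."""
    w, x, y, z = (q[..., i] for i in range(4))
    f1 = 2.0 * (x * z - w * y) - a_hat[..., 0]
    f2 = 2.0 * (y * z + w * x) - a_hat[..., 1]
    f3 = 1.0 - 2.0 * (x * x + y * y) - a_hat[..., 2]
    grad = np.stack(
        [
            -2.0 * y * f1 + 2.0 * x * f2,
            2.0 * z * f1 + 2.0 * w * f2 - 4.0 * x * f3,
            -2.0 * w * f1 + 2.0 * z * f2 - 4.0 * y * f3,
            2.0 * x * f1 + 2.0 * y * f2,
        ],
        axis=-1,
    )
    return grad


def _mag_objective(q: np.ndarray, m_hat: np.ndarray):
    """Heading objective against the tilt-compensated reference field (bx, 0, bz)."""
    w, x, y, z = (q[..., i] for i in range(4))
    # measured field in world frame
    h = quat.rotate(q, m_hat)
    bx = np.hypot(h[..., 0], h[..., 1])
    bz = h[..., 2]
    f1 = 2.0 * bx * (0.5 - y * y - z * z) + 2.0 * bz * (x * z - w * y) - m_hat[..., 0]
    f2 = 2.0 * bx * (x * y - w * z) + 2.0 * bz * (w * x + y * z) - m_hat[..., 1]
    f3 = 2.0 * bx * (w * y + x * z) + 2.0 * bz * (0.5 - x * x - y * y) - m_hat[..., 2]
    grad = np.stack(
        [
            -2.0 * bz * y * f1 + (-2.0 * bx * z + 2.0 * bz * x) * f2 + 2.0 * bx * y * f3,
            2.0 * bz * z * f1 + (2.0 * bx * y + 2.0 * bz * w) * f2
            + (2.0 * bx * z - 4.0 * bz * x) * f3,
            (-4.0 * bx * y - 2.0 * bz * w) * f1 + (2.0 * bx * x + 2.0 * bz * z) * f2
            + (2.0 * bx * w - 4.0 * bz * y) * f3,
            (-4.0 * bx * z + 2.0 * bz * x) * f1 + (-2.0 * bx * w + 2.0 * bz * y) * f2
            + 2.0 * bx * x * f3,
        ],
        axis=-1,
    )
    return grad


def _madgwick_step(q: np.ndarray, accel: np.ndarray, gyro_rad: np.ndarray,
                   beta: float, dt: float, mag: np.ndarray | None = None,
                   accel_gate: float = 0.0, gyro_gate_rad: float = 0.0) -> np.ndarray:
    """One Madgwick update; batched over leading axes. Gyro in rad/s."""
    omega = np.concatenate([np.zeros_like(gyro_rad[..., :1]), gyro_rad], axis=-1)
    qdot = 0.5 * quat.multiply(q, omega)
    a_norm = np.linalg.norm(accel, axis=-1, keepdims=True)
    valid = a_norm[..., 0] > 1e-12
    if accel_gate > 0.0:
        valid = valid & (np.abs(a_norm[..., 0] / GRAVITY - 1.0) <= accel_gate)
    if gyro_gate_rad > 0.0:
        valid = valid & (np.linalg.norm(gyro_rad, axis=-1) <= gyro_gate_rad)
    if beta > 0.0 and np.any(valid):
        a_hat = np.where(a_norm > 1e-12, accel / np.where(a_norm == 0, 1, a_norm), 0.0)
        grad = _gravity_objective(q, a_hat)
        if mag is not None:
            m_norm = np.linalg.norm(mag, axis=-1, keepdims=True)
            m_ok = m_norm[..., 0] > 1e-12
            if np.any(m_ok):
                m_hat = np.where(m_norm > 1e-12, mag / np.where(m_norm == 0, 1, m_norm), 0.0)
                grad = grad + np.where(m_ok[..., None], _mag_objective(q, m_hat), 0.0)
        g_norm = np.linalg.norm(grad, axis=-1, keepdims=True)
        step = np.where(g_norm > 1e-12, grad / np.where(g_norm == 0, 1, g_norm), 0.0)
        qdot = qdot - beta * np.where(valid[..., None], step, 0.0)
    return quat.normalize(q + qdot * dt)


def madgwick_update(q: np.ndarray, sample: ImuSample, beta: float, dt: float) -> np.ndarray:
    """Single Madgwick IMU update (gyro in deg/s). Returns a unit quaternion."""
    if dt <= 0:
        raise FusionError("dt must be positive")
    accel = np.asarray(sample.accel, dtype=float)
    if np.linalg.norm(accel) <= 1e-12:
        warnings.warn("zero-norm accelerometer sample: gyro-only integration for this step")
    return _madgwick_step(np.asarray(q, dtype=float), accel,
                          np.asarray(sample.gyro, dtype=float) * DEG, beta, dt)


def _fuse_madgwick(series: ImuSeries, params: FusionParams) -> np.ndarray:
    t = series.t
    gyro = series.gyro * DEG
    accel = series.accel
    mag = series.mag if (params.use_mag and series.mag is not None) else None
    n = len(t)
    q = np.empty((n, 4))
    q[0] = _tilt_from_accel(accel[0]) if params.beta > 0 else quat.IDENTITY
    for i in range(1, n):
        dt = t[i] - t[i - 1]
        in_warmup = (t[i] - t[0]) < params.warmup_s
        beta = params.warmup_beta if (in_warmup and params.beta > 0) else params.beta
        q[i] = _madgwick_step(q[i - 1], accel[i], gyro[i], beta, dt,
                              None if mag is None else mag[i],
                              accel_gate=params.accel_gate,
                              gyro_gate_rad=params.gyro_gate_dps * DEG)
    return q


def _fuse_complementary(series: ImuSeries, params: FusionParams) -> np.ndarray:
    t = series.t
    fs = series.rate
    nyq = fs / 2.0
    wn = min(params.lowpass_hz / nyq, 0.99)
    b, a = butter(2, wn)
    acc = filtfilt(b, a, series.accel, axis=0) if len(t) > 15 else series.accel
    pitch = np.arctan2(-acc[:, 0], np.hypot(acc[:, 1], acc[:, 2]))
    roll = np.arctan2(acc[:, 1], np.sqrt(acc[:, 2] ** 2 + 0.01 * acc[:, 0] ** 2)
                      * np.sign(acc[:, 2] + 0.1 * np.abs(acc[:, 0])))
    # world yaw rate: independent of yaw itself, so the tilt estimate suffices
    q_tilt = quat.from_euler_zyx(np.zeros_like(pitch), pitch, roll)
    omega_world_z = quat.rotate(q_tilt, series.gyro * DEG)[:, 2]
    yaw = np.concatenate([[0.0], np.cumsum(
        0.5 * (omega_world_z[1:] + omega_world_z[:-1]) * np.diff(t))])
    return quat.from_euler_zyx(yaw, pitch, roll)


def fuse_series(series: ImuSeries, method: str | None = None,
                params: FusionParams | None = None) -> OrientationSeries:
    """Estimate the sensor's orientation over time.

    ``method`` overrides ``params.method``; one orientation per sample.
    """
    params = params or FusionParams()
    method = method or params.method
    if series.t[-1] - series.t[0] < params.warmup_s:
        raise FusionError(
            f"series shorter than the {params.warmup_s:.2f} s warm-up window")
    if method == "madgwick":
        q = _fuse_madgwick(series, params)
    elif method == "complementary":
        q = _fuse_complementary(series, params)
    else:
        raise FusionError(f"unknown fusion method {method!r}")
    return OrientationSeries(series.sensor_id, series.t, q)


def fuse_session(streams: dict, method: str | None = None,
                 params: FusionParams | None = None) -> dict:
    """Fuse every stream of a session; returns sensor_id -> OrientationSeries."""
    return {sid: fuse_series(s, method, params) for sid, s in streams.items()}
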