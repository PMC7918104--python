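"""Orientation estimation: convergence, integration, round trips."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mobikit import quat
from mobikit.errors import FusionError
from mobikit.fusion import FusionParams, fuse_series, madgwick_update
from mobikit.synthetic import MotionParams, imu_from_trajectory, simulate_trajectory
from mobikit.types import ImuSample, ImuSeries

UP = np.array([0.0, 0.0, 9.81])


def _static_series(accel, n=300, rate=100.0, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    t = np.arange(n) / rate
    a = np.tile(accel, (n, 1)) + rng.normal(0, noise, (n, 3))
    return ImuSeries("s", t, a, np.zeros((n, 3)))


def test_stationary_sensor_converges_to_level():
    """Gravity along +Z must drive pitch and roll to zero for any gain."""
    dt = 0.01
    for beta in (0.1, 0.3, 0.5):
        q = np.array([0.9, 0.1, -0.3, 0.2]) / np.linalg.norm([0.9, 0.1, -0.3, 0.2])
        for _ in range(5000):
            q = madgwick_update(q, ImuSample(0.0, UP, np.zeros(3)), beta, dt)
        yaw, pitch, roll = quat.to_euler_zyx(q, degrees=True)
        # the normalised-gradient step has fixed size beta*dt, so the
        # converged state dithers within a band proportional to it
        tol = max(0.1, np.degrees(2.0 * beta * dt))
        assert abs(pitch) < tol and abs(roll) < tol, beta


def test_pure_yaw_rate_integrates_to_ninety_degrees():
    """90 deg/s about z for 1 s with beta=0 is pure gyro integration."""
    t = np.arange(0, 2.0, 0.01)
    s = ImuSeries("s", t, np.tile(UP, (len(t), 1)),
                  np.tile([0.0, 0.0, 90.0], (len(t), 1)))
    out = fuse_series(s, "madgwick", FusionParams(beta=0.0))
    yaw = quat.to_euler_zyx(out.q[100], degrees=True)[0]
    assert yaw == pytest.approx(90.0, abs=0.1)


def test_gravity_along_x_gives_ninety_degree_pitch():
    q = quat.IDENTITY.copy()
    sample = ImuSample(0.0, np.array([9.81, 0.0, 0.0]), np.zeros(3))
    for _ in range(5000):
        q = madgwick_update(q, sample, 0.3, 0.01)
    pitch = quat.to_euler_zyx(q, degrees=True)[1]
    assert abs(pitch) == pytest.approx(90.0, abs=0.5)


@pytest.mark.parametrize("method", ["madgwick", "complementary"])
def test_static_noisy_recording_small_tilt_error(method):
    """sigma = 0.05 m/s^2 accel noise: pitch/roll RMSE < 1 deg after warm-up."""
    s = _static_series(UP, n=500, noise=0.05)
    out = fuse_series(s, method)
    eul = quat.to_euler_zyx(out.q[100:], degrees=True)
    rmse = np.sqrt(np.mean(eul[:, 1] ** 2 + eul[:, 2] ** 2))
    assert rmse < 1.0


@pytest.mark.parametrize("method, freq_hz", [
    ("madgwick", 0.5),
    ("complementary", 0.05),  # quasi-static regime: its gravity estimate is 0.5 Hz low-passed
])
def test_pitch_sinusoid_round_trip(method, freq_hz, model):
    """A +-20 deg pitch oscillation is recovered within 2 deg RMSE."""
    t = np.arange(0, max(6.0, 2.5 / freq_hz), 0.01)
    # raised-cosine oscillation: starts at rest, amplitude 20 deg peak-to-zero
    pitch = np.deg2rad(20.0) * 0.5 * (1 - np.cos(2 * np.pi * freq_hz * t))
    q = quat.from_euler_zyx(np.zeros_like(t), pitch, np.zeros_like(t))
    from mobikit.types import PostureSeries
    posture = PostureSeries(model=model, t=t,
                            seg_q={s.name: q for s in model.segments},
                            root_pos=np.zeros((len(t), 3)))
    from mobikit.kinematics import forward_kinematics
    posture.joints = forward_kinematics(posture.seg_q, model, len(t))
    rec = imu_from_trajectory(posture, model)
    out = fuse_series(rec.streams["L5"], method)
    est = quat.to_euler_zyx(out.q, degrees=True)[:, 1]
    err = est[100:] - np.degrees(pitch)[100:]
    assert np.sqrt(np.mean(err ** 2)) < 2.0


def test_beta_zero_equals_raw_gyro_integration():
    rng = np.random.default_rng(5)
    n = 200
    t = np.arange(n) / 100.0
    gyro = rng.normal(0, 40, (n, 3))
    s = ImuSeries("s", t, np.tile(UP, (n, 1)), gyro)
    fused = fuse_series(s, "madgwick", FusionParams(beta=0.0))
    q = quat.IDENTITY.copy()
    manual = [q]
    for i in range(1, n):
        omega = np.concatenate([[0.0], np.deg2rad(gyro[i])])
        q = quat.normalize(q + 0.5 * quat.multiply(q, omega) * 0.01)
        manual.append(q)
    err = np.degrees(quat.angle_between(fused.q, np.array(manual)))
    assert err.max() < 1e-4  # identical up to floating-point op order


def test_series_shorter_than_warmup_rejected():
    s = _static_series(UP, n=50)
    with pytest.raises(FusionError):
        fuse_series(s, "madgwick", FusionParams(warmup_s=1.0))


def test_noise_free_trajectory_round_trip_under_two_degrees(model, swap_sim):
    """Full-dynamics recording: fused orientation error < 2 deg RMS."""
    posture, _ = swap_sim
    rec = imu_from_trajectory(posture, model, task="swap")
    for sid, name in model.sensor_map.items():
        out = fuse_series(rec.streams[sid], "madgwick")
        err = np.degrees(quat.angle_between(out.q, posture.seg_q[name]))
        assert np.sqrt(np.mean(err[100:] ** 2)) < 2.0, name


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.lists(st.floats(-200, 200), min_size=3, max_size=3),
       st.floats(0.0, 1.0))
def test_quaternion_norm_preserved_every_update(gyro, beta):
    q = quat.normalize(np.array([0.7, -0.2, 0.5, 0.1]))
    q = madgwick_update(q, ImuSample(0.0, UP, np.array(gyro)), beta, 0.01)
    assert abs(np.linalg.norm(q) - 1.0) < 1e-9


def test_level_sensor_measures_gravity_as_positive_z(model):
    """Frame convention: a level static sensor reads accel = +9.81 on z."""
    posture, _ = simulate_trajectory(MotionParams(task="stance"), model)
    rec = imu_from_trajectory(posture, model)
    np.testing.assert_allclose(rec.streams["L5"].accel[50:-50].mean(axis=0),
                               UP, atol=1e-6)
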