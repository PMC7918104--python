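"""Sensor-to-segment calibration: recovery of injected misalignments."""

import numpy as np
import pytest

from mobikit import quat
from mobikit.calibration import (CalibrationConfig, CalibrationResult,
                                 apply_calibration, calibrate_session,
                                 choose_calibration, stage1_vertical_alignment,
                                 stage2_front_direction)
from mobikit.errors import (AmbiguousMovementError, CalibrationError, MappingError,
                            UnstableStanceError)
from mobikit.fusion import fuse_series
from mobikit.synthetic import (MotionParams, draw_misalignments, imu_from_trajectory,
                               simulate_trajectory)
from mobikit.types import ImuSeries, OrientationSeries, SessionRecord

from conftest import stance_window


def _calibrate(rec, model, cfg=None):
    stance, movement = stance_window(rec)
    return calibrate_session(rec, model, stance, movement, cfg)


def test_aligned_sensors_get_identity_correction(cal_sim, model):
    rec, _, _ = cal_sim
    cal = _calibrate(rec, model)
    for sid, q in cal.corrections.items():
        assert np.degrees(quat.angle_between(q, quat.IDENTITY)) < 0.1, sid


def test_known_tilt_recovered(cal_sim, model):
    """A 15-degree mounting tilt about the sensor X axis is recovered."""
    _, posture, _ = cal_sim
    mis = {"THIGH_L": quat.from_axis_angle(np.array([1.0, 0, 0]), np.deg2rad(15.0))}
    rec = imu_from_trajectory(posture, model, misalignments=mis)
    cal = _calibrate(rec, model)
    err = np.degrees(quat.angle_between(cal.corrections["THIGH_L"], mis["THIGH_L"]))
    assert err < 0.5


def test_known_yaw_offset_recovered(cal_sim, model):
    """A 30-degree mounting yaw is recovered by the lean-squat stage."""
    _, posture, _ = cal_sim
    mis = {"C7_TH1": quat.from_axis_angle(np.array([0.0, 0, 1.0]), np.deg2rad(30.0))}
    rec = imu_from_trajectory(posture, model, misalignments=mis)
    cal = _calibrate(rec, model)
    err = np.degrees(quat.angle_between(cal.corrections["C7_TH1"], mis["C7_TH1"]))
    assert err < 1.0


def test_swaying_stance_rejected(model):
    """+-10 degree sway during the stance window exceeds the dispersion gate."""
    t = np.arange(0, 2.0, 0.01)
    pitch = np.deg2rad(10.0) * np.sin(2 * np.pi * 0.8 * t)
    accel = np.stack([-9.81 * np.sin(pitch), np.zeros_like(t),
                      9.81 * np.cos(pitch)], axis=1)
    rec = SessionRecord("s", "calibration_start",
                        {"L5": ImuSeries("L5", t, accel, np.zeros((len(t), 3)))})
    with pytest.raises(UnstableStanceError):
        stage1_vertical_alignment(rec, window=(0.0, 2.0))


def test_pure_lateral_lean_is_ambiguous(model):
    """A lateral lean moves no leg sensor, so stage 2 must fail."""
    p = MotionParams(task="calibration")
    posture, ev = simulate_trajectory(p, model)
    # replace the sagittal movement by a lateral lean: roll instead of pitch
    t = posture.t
    move = t >= ev["movement_start"]
    for name in ("pelvis", "trunk"):
        eul = quat.to_euler_zyx(posture.seg_q[name], degrees=False)
        roll = np.where(move, eul[:, 1], 0.0)  # reuse the pitch profile as roll
        posture.seg_q[name] = quat.from_euler_zyx(eul[:, 0], 0.0 * roll, roll)
    # legs stay perfectly still
    for name in ("thigh_l", "thigh_r", "shank_l", "shank_r"):
        posture.seg_q[name] = np.tile(posture.seg_q[name][0], (len(t), 1))
    rec = imu_from_trajectory(posture, model)
    s1 = stage1_vertical_alignment(rec, window=(0.2, 1.8))
    with pytest.raises(AmbiguousMovementError):
        stage2_front_direction(rec, s1, model, window=(ev["movement_start"], t[-1]))


def test_end_of_session_preferred_start_as_fallback():
    good = CalibrationResult({"a": quat.IDENTITY}, {"a": 1.0}, {"a": 0.95},
                             source="session_end")
    bad_end = CalibrationResult({"a": quat.IDENTITY}, {"a": 8.0}, {"a": 0.95},
                                source="session_end")
    start = CalibrationResult({"a": quat.IDENTITY}, {"a": 1.0}, {"a": 0.95},
                              source="session_start")
    assert choose_calibration(start, good).source == "session_end"
    assert choose_calibration(start, bad_end).source == "session_start"
    with pytest.warns(UserWarning):
        assert choose_calibration(start, None).source == "session_start"
    with pytest.raises(CalibrationError):
        choose_calibration(bad_end.__class__({"a": quat.IDENTITY}, {"a": 9.0},
                                             {"a": 0.5}, source="session_start"),
                           bad_end)


def test_identity_correction_preserves_orientations(cal_sim, model):
    rec, posture, _ = cal_sim
    cal = _calibrate(rec, model)
    series = OrientationSeries("L5", posture.t, posture.seg_q["pelvis"])
    out = apply_calibration(series, cal, zero_heading=False)
    err = np.degrees(quat.angle_between(out.q, series.q))
    assert err.max() < 0.2


def test_missing_sensor_raises_mapping_error_naming_it(cal_sim, model):
    rec, posture, _ = cal_sim
    cal = _calibrate(rec, model)
    series = OrientationSeries("UNKNOWN", posture.t, posture.seg_q["pelvis"])
    with pytest.raises(MappingError, match="UNKNOWN"):
        apply_calibration(series, cal)


def test_random_misalignments_recovered_within_budget(cal_sim, model):
    """Round trip: inject up to 40 deg mounting error, calibrate, compare."""
    _, posture, _ = cal_sim
    rng = np.random.default_rng(21)
    for _ in range(5):
        mis = draw_misalignments(model, 40.0, rng)
        rec = imu_from_trajectory(posture, model, misalignments=mis)
        cal = _calibrate(rec, model)
        for sid in mis:
            err = np.degrees(quat.angle_between(cal.corrections[sid], mis[sid]))
            assert err < 1.5, sid


def test_calibrated_movement_matches_ground_truth(cal_sim, model):
    """Misalign, calibrate, fuse the lean-squat recording: calibrated
    segment orientations match the generating trajectory within 1.5 deg
    RMS."""
    _, cal_posture, _ = cal_sim
    rng = np.random.default_rng(8)
    mis = draw_misalignments(model, 30.0, rng)
    cal_rec = imu_from_trajectory(cal_posture, model, misalignments=mis)
    cal = _calibrate(cal_rec, model)
    for sid, name in model.sensor_map.items():
        seg = apply_calibration(fuse_series(cal_rec.streams[sid], "madgwick"), cal)
        err = np.degrees(quat.angle_between(seg.q, cal_posture.seg_q[name]))
        assert np.sqrt(np.mean(err[100:] ** 2)) < 1.5, name


def test_calibrated_full_task_within_two_degrees(cal_sim, swap_sim, model):
    """Misalign, calibrate, fuse a full SWAP recording: segment
    orientations match the generating trajectory within 2 deg RMS."""
    _, cal_posture, _ = cal_sim
    posture, _ = swap_sim
    rng = np.random.default_rng(8)
    mis = draw_misalignments(model, 30.0, rng)
    cal_rec = imu_from_trajectory(cal_posture, model, misalignments=mis)
    cal = _calibrate(cal_rec, model)
    rec = imu_from_trajectory(posture, model, misalignments=mis, task="swap")
    for sid, name in model.sensor_map.items():
        seg = apply_calibration(fuse_series(rec.streams[sid], "madgwick"), cal)
        err = np.degrees(quat.angle_between(seg.q, posture.seg_q[name]))
        assert np.sqrt(np.mean(err[100:] ** 2)) < 2.0, name
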