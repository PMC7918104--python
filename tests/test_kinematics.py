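"""Forward kinematics, COM, walk translation, foot forces."""

import numpy as np
import pytest

from mobikit import quat
from mobikit.errors import ModelError
from mobikit.kinematics import (KinematicsConfig, compute_com, foot_forces,
                                forward_kinematics, reconstruct_posture)
from mobikit.synthetic import MotionParams, simulate_trajectory
from mobikit.types import GRAVITY, BodyModel, OrientationSeries, PostureSeries, Segment


def _upright_series(model, n=120, rate=100.0):
    t = np.arange(n) / rate
    q = np.tile(quat.IDENTITY, (n, 1))
    return {s.name: OrientationSeries(s.name, t, q.copy()) for s in model.segments}


def test_standing_chain_heights_are_analytic(model):
    """All segments upright: joint heights telescope the segment lengths."""
    posture = reconstruct_posture(_upright_series(model), model)
    leg = model["thigh_l"].length + model["shank_l"].length
    head_top = posture.joints["trunk"]["distal"][0]
    expected = leg + model["pelvis"].length + model["trunk"].length
    assert head_top[2] == pytest.approx(expected, abs=1e-9)
    assert posture.joints["shank_l"]["distal"][0][2] == pytest.approx(0.0, abs=1e-9)


def test_sitting_like_pose_displaces_knee_by_thigh_length(model):
    """Thigh pitched 90 deg, shank vertical: knee sits one thigh-length forward."""
    series = _upright_series(model)
    n = len(series["pelvis"].t)
    q_thigh = np.tile(quat.from_euler_zyx(0.0, -np.pi / 2, 0.0), (n, 1))
    for name in ("thigh_l", "thigh_r"):
        series[name] = OrientationSeries(name, series[name].t, q_thigh.copy())
    posture = reconstruct_posture(series, model, anchor="none")
    hip = posture.joints["thigh_l"]["proximal"][0]
    knee = posture.joints["thigh_l"]["distal"][0]
    assert knee[0] - hip[0] == pytest.approx(model["thigh_l"].length, abs=1e-9)
    assert knee[2] == pytest.approx(hip[2], abs=1e-9)


def test_single_segment_pitch_closed_form():
    """One segment pitched 10 deg: top at (L sin10, 0, L cos10), base affixed."""
    m = BodyModel([Segment(name="body", length=1.7, mass_fraction=0.9,
                           sensor_id="S1")], total_mass=70.0)
    n, rate = 60, 50.0
    t = np.arange(n) / rate
    q = np.tile(quat.from_euler_zyx(0.0, np.deg2rad(10.0), 0.0), (n, 1))
    posture = reconstruct_posture({"body": OrientationSeries("S1", t, q)}, m)
    top = posture.joints["body"]["distal"][0]
    L = 1.7
    np.testing.assert_allclose(top, [L * np.sin(np.deg2rad(10)), 0.0,
                                     L * np.cos(np.deg2rad(10))], atol=1e-9)
    np.testing.assert_allclose(posture.joints["body"]["proximal"][0], 0.0, atol=1e-12)


def test_com_symmetric_standing_is_centred(model):
    posture = reconstruct_posture(_upright_series(model), model)
    assert abs(posture.com[0][1]) < 1e-9


def test_com_two_segment_hand_computed_weighted_sum():
    m = BodyModel([
        Segment(name="lower", length=1.0, mass_fraction=0.5, com_offset=0.5,
                sensor_id="A"),
        Segment(name="upper", length=1.0, mass_fraction=0.5, com_offset=0.5,
                parent="lower", sensor_id="B"),
    ], total_mass=60.0)
    n = 30
    t = np.arange(n) / 100.0
    series = {name: OrientationSeries(name, t, np.tile(quat.IDENTITY, (n, 1)))
              for name in ("lower", "upper")}
    posture = reconstruct_posture({"A": series["lower"], "B": series["upper"]}, m,
                                  anchor="none")
    # lower COM at 0.5, upper COM at 1.5 -> equal masses average to 1.0
    assert posture.com[0][2] == pytest.approx(1.0, abs=1e-12)


def test_com_normalises_partial_mass_fractions(model):
    """Fractions summing to ~0.94 (arms excluded) must be renormalised."""
    posture = reconstruct_posture(_upright_series(model), model)
    brute = np.zeros(3)
    total = 0.0
    for seg in model.segments:
        com = (posture.joints[seg.name]["proximal"][0]
               + quat.rotate(posture.seg_q[seg.name][0],
                             seg.axis_local * seg.length * seg.com_offset))
        brute += seg.mass_fraction * com
        total += seg.mass_fraction
    np.testing.assert_allclose(posture.com[0], brute / total, atol=1e-12)


def test_all_zero_mass_fractions_rejected():
    m = BodyModel([Segment(name="a", length=1.0, mass_fraction=0.0, sensor_id="A")])
    n = 20
    t = np.arange(n) / 100.0
    with pytest.raises(ModelError):
        reconstruct_posture(
            {"A": OrientationSeries("A", t, np.tile(quat.IDENTITY, (n, 1)))}, m,
            anchor="none")


def _recon_from_truth(posture, model, anchor="auto"):
    series = {name: OrientationSeries(name, posture.t, posture.seg_q[name])
              for name in posture.seg_q}
    return reconstruct_posture(series, model, anchor=anchor)


@pytest.mark.parametrize("swing, tol", [(0.05, 0.10), (0.0, 0.15)])
def test_walk_translation_recovers_travel(model, swing, tol):
    """4 x 0.5 m steps: recovered travel within tolerance (lifted and shuffled)."""
    p = MotionParams(task="walk", walk_distance_m=2.0, step_length_m=0.5,
                     swing_height_m=swing)
    posture, _ = simulate_trajectory(p, model)
    recon = _recon_from_truth(posture, model)
    travel = np.linalg.norm(recon.root_pos[-1, :2] - recon.root_pos[0, :2])
    assert travel == pytest.approx(2.0, rel=tol)


def test_standing_still_translation_is_zero(model):
    posture, _ = simulate_trajectory(MotionParams(task="stance"), model)
    recon = _recon_from_truth(posture, model)
    drift = np.linalg.norm(recon.root_pos - recon.root_pos[0], axis=1)
    assert drift.max() < 0.01


def test_quiet_stance_forces_split_half_mg(model):
    posture, _ = simulate_trajectory(MotionParams(task="stance"), model)
    forces = foot_forces(posture.com, model, posture)
    mid = slice(50, -50)
    half = model.total_mass * GRAVITY / 2.0
    assert np.allclose(forces.left[mid], half, atol=1.0)
    assert np.allclose(forces.right[mid], half, atol=1.0)
    assert set(forces.support[mid]) == {"double"}


def test_single_support_carries_full_weight(model):
    """One foot raised: the stance foot takes m g within 2 N."""
    posture, _ = simulate_trajectory(MotionParams(task="stance"), model)
    # raise the left foot by 10 cm artificially
    posture.joints["shank_l"]["distal"] = posture.joints["shank_l"]["distal"] + [0, 0, 0.10]
    forces = foot_forces(posture.com, model, posture)
    mid = slice(50, -50)
    assert np.allclose(forces.right[mid], model.total_mass * GRAVITY, atol=2.0)
    assert np.allclose(forces.left[mid], 0.0, atol=1e-9)
    assert set(forces.support[mid]) == {"right"}


def test_vertical_com_acceleration_scales_total_force(model):
    """COM accelerating up at 1 m/s^2: total force = m (g + 1)."""
    posture, _ = simulate_trajectory(MotionParams(task="stance"), model)
    t = posture.t
    com = posture.com.copy()
    com[:, 2] += 0.5 * 1.0 * t ** 2  # constant 1 m/s^2 upward
    forces = foot_forces(com, model, posture)
    mid = slice(60, -60)
    total = forces.left[mid] + forces.right[mid]
    assert np.allclose(total, model.total_mass * (GRAVITY + 1.0), atol=2.0)


def test_force_conservation_every_double_support_frame(model, swap_sim):
    """left + right equals m (g + a_com,z) whenever both feet are down."""
    posture, _ = swap_sim
    cfg = KinematicsConfig()
    forces = foot_forces(posture.com, model, posture, cfg)
    from scipy.signal import butter, filtfilt
    b, a = butter(2, cfg.smoothing_hz / (posture.rate / 2))
    az = np.gradient(np.gradient(filtfilt(b, a, posture.com[:, 2]), posture.t),
                     posture.t)
    expected = np.maximum(model.total_mass * (GRAVITY + az), 0.0)
    double = forces.support == "double"
    np.testing.assert_allclose((forces.left + forces.right)[double],
                               expected[double], atol=1e-6)


def test_reconstruction_matches_simulator_geometry(model, cal_sim):
    """Noise-free round trip from true orientations: joints within 2 cm RMS."""
    _, posture, _ = cal_sim
    recon = _recon_from_truth(posture, model)
    errs = []
    for name in posture.seg_q:
        for end in ("proximal", "distal"):
            d = recon.joints[name][end] - posture.joints[name][end]
            errs.append(np.linalg.norm(d, axis=1))
    rms = np.sqrt(np.mean(np.stack(errs) ** 2))
    assert rms < 0.02


def test_chain_joint_coincidence_invariant(model, swap_sim):
    """Child proximal joints coincide with the parent attachment point."""
    posture, _ = swap_sim
    recon = _recon_from_truth(posture, model)
    for seg in model.segments:
        if seg.parent in (None, "ground"):
            continue
        base = recon.joints[seg.parent][seg.attach]
        expected = base + quat.rotate(recon.seg_q[seg.parent], seg.attach_offset)
        np.testing.assert_allclose(recon.joints[seg.name]["proximal"], expected,
                                   atol=1e-9)
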