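"""Shared fixtures: synthetic recordings with known ground truth."""

import numpy as np
import pytest

from mobikit.io_model import default_body_model
from mobikit.synthetic import (MotionParams, SensorNoise, imu_from_trajectory,
                               simulate_trajectory)


@pytest.fixture(scope="session")
def model():
    return default_body_model()


@pytest.fixture(scope="session")
def cal_sim(model):
    """Noise-free calibration recording: (record, posture, events)."""
    posture, events = simulate_trajectory(MotionParams(task="calibration"), model)
    rec = imu_from_trajectory(posture, model, task="calibration_start")
    return rec, posture, events


@pytest.fixture(scope="session")
def swap_sim(model):
    """Noise-free SWAP trajectory: (posture, events)."""
    return simulate_trajectory(MotionParams(task="swap"), model)


@pytest.fixture(scope="session")
def tug_sim(model):
    """Noise-free TUG trajectory: (posture, events)."""
    return simulate_trajectory(MotionParams(task="tug"), model)


@pytest.fixture(scope="session")
def subject_sessions(model):
    """One noisy 50 Hz subject: both calibrations plus SWAP and TUG."""
    from dataclasses import replace

    from mobikit.synthetic import draw_misalignments

    rng = np.random.default_rng(11)
    mis = draw_misalignments(model, 10.0, rng)
    noise = SensorNoise(accel_sigma=0.05, gyro_sigma=0.2, gyro_bias=0.1)
    base = MotionParams(task="swap", rate_hz=50.0)
    sessions = {}
    for task, rec_task in (("calibration", "calibration_start"), ("swap", "swap"),
                           ("tug", "tug"), ("calibration", "calibration_end")):
        posture, _ = simulate_trajectory(replace(base, task=task), model)
        sessions[rec_task] = imu_from_trajectory(posture, model, noise, mis, rng,
                                                 task=rec_task, subject_id="subj")
    return sessions


def stance_window(record):
    """Default stance/movement windows for a simulated calibration record."""
    t0, t1 = record.common_window()
    return (t0 + 0.2, t0 + 1.8), (t0 + 2.0, t1)
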