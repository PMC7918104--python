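"""Two-stage sensor-to-segment calibration.

Stage 1 (upright stance): the mean accelerometer direction during quiet
standing is the segment's vertical, so the sensor Z axis can be aligned
with the segment Z axis.  Stage 2 (forward lean + squat): both movements
are sagittal rotations, so the dominant rotation axis of the stage-1
corrected angular velocity identifies the segment pitch (+Y) axis; the
sign is fixed by the expected flexion direction of the segment (trunk
and shanks tip forward, thighs flex the other way).  Together these fix
the full sensor->segment rotation.

The calibration sequence is recorded twice, at the start and at the end
of a session; the end-of-session result is preferred unless its quality
scores fail the configured thresholds.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
from scipy.spatial.transform import Rotation

from . import quat
from .errors import (AmbiguousMovementError, CalibrationError, MappingError,
                     UnstableStanceError)
from .types import BodyModel, OrientationSeries, SessionRecord

log = logging.getLogger(__name__)

DEG = np.pi / 180.0


@dataclass
class CalibrationConfig:
    """Quality thresholds and windows (config keys ``calibration.*``)."""

    stance_window_s: float = 1.0
    max_gravity_dispersion_deg: float = 5.0
    min_axis_energy: float = 0.8
    min_excursion_deg: float = 10.0
    heading_window_s: float = 0.5


@dataclass
class CalibrationResult:
    """Per-sensor sensor->segment corrections with quality scores.

    ``corrections[sensor_id]`` is a unit quaternion q such that
    ``v_segment = q * v_sensor * q^-1``.
    """

    corrections: Dict[str, np.ndarray]
    dispersion_deg: Dict[str, float] = field(default_factory=dict)
    axis_energy: Dict[str, float] = field(default_factory=dict)
    source: str = "session_end"

    def quality_ok(self, cfg: CalibrationConfig) -> bool:
        return all(d <= cfg.max_gravity_dispersion_deg for d in self.dispersion_deg.values()) \
            and all(e >= cfg.min_axis_energy for e in self.axis_energy.values())


def _window(t: np.ndarray, window: Optional[Tuple[float, float]]) -> np.ndarray:
    if window is None:
        return np.ones(len(t), dtype=bool)
    mask = (t >= window[0]) & (t <= window[1])
    if not np.any(mask):
        raise CalibrationError("requested window contains no samples")
    return mask


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Minimal rotation quaternion taking unit vector a to unit vector b."""
    c = float(np.dot(a, b))
    if c > 1.0 - 1e-12:
        return quat.IDENTITY.copy()
    if c < -1.0 + 1e-12:
        # 180 deg: any axis orthogonal to a
        axis = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-8:
            axis = np.cross(a, [0.0, 1.0, 0.0])
        return quat.from_axis_angle(axis, np.pi)
    axis = np.cross(a, b)
    return quat.from_axis_angle(axis, np.arccos(np.clip(c, -1, 1)))


def stage1_vertical_alignment(stance: SessionRecord,
                              window: Optional[Tuple[float, float]] = None,
                              cfg: Optional[CalibrationConfig] = None) -> Dict[str, dict]:
    """Align each sensor's measured gravity with the segment vertical.

    Returns sensor_id -> {"q1": partial correction quaternion,
    "dispersion_deg": RMS angular scatter of the gravity samples}.
    The partial correction maps the mean measured gravity-reaction
    direction onto the segment +Z (up) axis.
    """
    cfg = cfg or CalibrationConfig()
    out: Dict[str, dict] = {}
    ez = np.array([0.0, 0.0, 1.0])
    for sid, s in stance.streams.items():
        mask = _window(s.t, window)
        dirs = s.accel[mask]
        norms = np.linalg.norm(dirs, axis=1, keepdims=True)
        dirs = dirs / norms
        mean_dir = dirs.mean(axis=0)
        mean_dir /= np.linalg.norm(mean_dir)
        ang = np.arccos(np.clip(dirs @ mean_dir, -1.0, 1.0))
        dispersion = float(np.sqrt(np.mean(ang ** 2)) / DEG)
        if dispersion > cfg.max_gravity_dispersion_deg:
            raise UnstableStanceError(
                f"sensor {sid}: gravity dispersion {dispersion:.1f} deg exceeds "
                f"{cfg.max_gravity_dispersion_deg:.1f} deg (unstable stance)")
        out[sid] = {"q1": _rotation_between(mean_dir, ez), "dispersion_deg": dispersion}
    return out


def stage2_front_direction(lean_squat: SessionRecord, stage1: Dict[str, dict],
                           model: BodyModel,
                           window: Optional[Tuple[float, float]] = None,
                           cfg: Optional[CalibrationConfig] = None,
                           source: str = "session_end") -> CalibrationResult:
    """Identify each segment's pitch axis from the lean-and-squat movement.

    The principal axis of the stage-1-corrected angular velocity over the
    window is taken as the segment +Y axis; its sign is chosen so the
    cumulative sagittal rotation matches the segment's expected flexion
    direction.  Requires a dominant-axis energy fraction >= the
    configured threshold and a minimum total excursion.
    """
    cfg = cfg or CalibrationConfig()
    sensor_map = model.sensor_map
    corrections: Dict[str, np.ndarray] = {}
    dispersion: Dict[str, float] = {}
    energy: Dict[str, float] = {}
    ez = np.array([0.0, 0.0, 1.0])
    for sid, s in lean_squat.streams.items():
        if sid not in stage1:
            raise MappingError(f"sensor {sid} missing from stage-1 result")
        if sid not in sensor_map:
            raise MappingError(f"sensor {sid} not assigned to any segment in the model")
        seg = model[sensor_map[sid]]
        q1 = stage1[sid]["q1"]
        mask = _window(s.t, window)
        t = s.t[mask]
        omega = quat.rotate(q1, s.gyro[mask] * DEG)  # rad/s, stage-1 corrected frame
        cov = omega.T @ omega
        evals, evecs = np.linalg.eigh(cov)
        frac = float(evals[-1] / max(np.sum(evals), 1e-30))
        axis = evecs[:, -1]
        signed = omega @ axis
        cum = np.concatenate([[0.0], np.cumsum(0.5 * (signed[1:] + signed[:-1]) * np.diff(t))])
        excursion = float(np.max(np.abs(cum)) / DEG)
        if excursion < cfg.min_excursion_deg:
            raise AmbiguousMovementError(
                f"sensor {sid}: total sagittal excursion {excursion:.1f} deg below "
                f"{cfg.min_excursion_deg:.1f} deg (movement not performed?)")
        if frac < cfg.min_axis_energy:
            raise AmbiguousMovementError(
                f"sensor {sid}: dominant-axis energy fraction {frac:.2f} below "
                f"{cfg.min_axis_energy:.2f}")
        # sign: the extremal cumulative rotation must match the flexion direction
        extremum = cum[int(np.argmax(np.abs(cum)))]
        if extremum * seg.flexion_sign < 0:
            axis = -axis
        # project out the vertical component fixed by stage 1
        y_axis = axis - np.dot(axis, ez) * ez
        ny = np.linalg.norm(y_axis)
        if ny < 0.3:  # rotation axis nearly vertical: not a sagittal movement
            raise AmbiguousMovementError(
                f"sensor {sid}: dominant rotation axis is near-vertical")
        y_axis /= ny
        x_axis = np.cross(y_axis, ez)
        # rows of the (corrected frame -> segment frame) matrix
        r2 = np.stack([x_axis, y_axis, ez])
        q2 = quat.from_rotation(Rotation.from_matrix(r2))
        corrections[sid] = quat.normalize(quat.multiply(q2, q1))
        dispersion[sid] = stage1[sid]["dispersion_deg"]
        energy[sid] = frac
    return CalibrationResult(corrections, dispersion, energy, source=source)


def choose_calibration(start: Optional[CalibrationResult],
                       end: Optional[CalibrationResult],
                       cfg: Optional[CalibrationConfig] = None) -> CalibrationResult:
    """Prefer the end-of-session calibration; fall back to the start one.

    The end result is used unless its quality scores fail the thresholds,
    in which case the start result is used (and vice versa).
    """
    cfg = cfg or CalibrationConfig()
    if start is None and end is None:
        raise CalibrationError("no calibration result available")
    if end is None:
        warnings.warn("only the start-of-session calibration is available; using it")
        return start
    if start is None:
        return end
    if end.quality_ok(cfg):
        return end
    if start.quality_ok(cfg):
        log.info("end-of-session calibration failed quality checks; using start-of-session")
        return start
    raise CalibrationError("both start and end calibrations fail quality thresholds")


def _heading_angle(q: np.ndarray) -> float:
    """Heading from the segment +Y (left) axis; robust at pitch +-90 deg."""
    y = quat.rotate(q, np.array([0.0, 1.0, 0.0]))
    y = np.atleast_2d(y).mean(axis=0)
    return float(np.arctan2(-y[0], y[1]))


def apply_calibration(orient: OrientationSeries, cal: CalibrationResult,
                      zero_heading: bool = True,
                      heading_window_s: float = 0.5) -> OrientationSeries:
    """Map a sensor orientation series onto its body segment.

    ``q_segment = q_sensor * q_correction^-1``; when ``zero_heading`` the
    world yaw is then zeroed over the initial quiet window so the
    subject's front direction at the start of the recording is world +X
    (heading is unobservable without a magnetometer, so each recording
    carries its own front reference).
    """
    if orient.sensor_id not in cal.corrections:
        raise MappingError(f"sensor {orient.sensor_id} missing from calibration result")
    corr = cal.corrections[orient.sensor_id]
    q_seg = quat.multiply(orient.q, quat.conjugate(corr)[None, :])
    if zero_heading:
        mask = orient.t <= orient.t[0] + heading_window_s
        psi = _heading_angle(q_seg[mask])
        rz = quat.from_axis_angle(np.array([0.0, 0.0, 1.0]), -psi)
        q_seg = quat.multiply(rz[None, :], q_seg)
    return OrientationSeries(orient.sensor_id, orient.t, quat.normalize(q_seg))


def calibrate_session(stance_and_movement: SessionRecord, model: BodyModel,
                      stance_window: Tuple[float, float],
                      movement_window: Tuple[float, float],
                      cfg: Optional[CalibrationConfig] = None,
                      source: str = "session_end") -> CalibrationResult:
    """Run both stages on one calibration recording."""
    cfg = cfg or CalibrationConfig()
    s1 = stage1_vertical_alignment(stance_and_movement, stance_window, cfg)
    return stage2_front_direction(stance_and_movement, s1, model, movement_window, cfg,
                                  source=source)
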