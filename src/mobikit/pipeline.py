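"""End-to-end orchestration: raw sessions -> features -> study report.

``run_subject`` executes fusion -> sensor-to-segment calibration ->
posture reconstruction -> phase segmentation -> feature extraction for
one subject's recordings, collecting a manifest of per-stage choices.
``run_study`` evaluates a labelled cohort over the full hyperparameter
grid per input set and aggregates the marginal-mean and summary tables.

Calibration recordings are expected to begin with quiet upright stance
followed by the forward-lean + squat sequence; the stance window length
comes from the calibration config.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

from . import metrics
from .calibration import (CalibrationConfig, CalibrationResult, apply_calibration,
                          calibrate_session, choose_calibration)
from .classifier import Dataset, grid_evaluate
from .errors import CalibrationError, MobikitError
from .features import FeatureConfig, swap4_features, swap82_features, tug6_features
from .fusion import FusionParams, fuse_session
from .kinematics import KinematicsConfig, reconstruct_posture
from .segmentation import Thresholds, detect_swap_phases, detect_tug_phases
from .types import BodyModel, SessionRecord

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All stage configurations in one place."""

    fusion: FusionParams = field(default_factory=FusionParams)
    calibration: CalibrationConfig = field(default_factory=CalibrationConfig)
    kinematics: KinematicsConfig = field(default_factory=KinematicsConfig)
    thresholds: Thresholds = field(default_factory=Thresholds)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    stance_settle_s: float = 0.2   # ignored lead-in before the stance window


def _calibrate(record: SessionRecord, model: BodyModel, cfg: PipelineConfig,
               source: str) -> CalibrationResult:
    t0, t1 = record.common_window()
    stance = (t0 + cfg.stance_settle_s,
              t0 + cfg.stance_settle_s + cfg.calibration.stance_window_s)
    movement = (stance[1] + cfg.stance_settle_s, t1)
    return calibrate_session(record, model, stance, movement,
                             cfg.calibration, source=source)


def run_subject(sessions: Dict[str, SessionRecord], model: BodyModel,
                config: Optional[PipelineConfig] = None
                ) -> Tuple[dict, dict]:
    """Process one subject's recordings into feature vectors.

    ``sessions`` maps task names (``calibration_start``,
    ``calibration_end``, ``swap``, ``tug``) to records.  Returns
    ``(features, manifest)`` where features holds the SWAP4 / SWAP82 /
    TUG6 vectors that could be computed.
    """
    config = config or PipelineConfig()
    manifest: dict = {"stages": {}}
    cals = {}
    for key, source in (("calibration_start", "session_start"),
                        ("calibration_end", "session_end")):
        if key in sessions:
            try:
                cals[source] = _calibrate(sessions[key], model, config, source)
            except CalibrationError as exc:
                manifest["stages"][f"calibrate_{source}"] = f"failed: {exc}"
                log.warning("calibration %s failed: %s", source, exc)
    if not cals:
        raise CalibrationError("no usable calibration recording for this subject")
    cal = choose_calibration(cals.get("session_start"), cals.get("session_end"),
                             config.calibration)
    manifest["calibration_source"] = cal.source
    manifest["calibration_quality"] = {
        "dispersion_deg": dict(cal.dispersion_deg),
        "axis_energy": dict(cal.axis_energy),
    }

    features: dict = {}
    for task, detect in (("swap", detect_swap_phases), ("tug", detect_tug_phases)):
        if task not in sessions:
            continue
        rec = sessions[task]
        try:
            oriented = fuse_session(rec.streams, params=config.fusion)
            segment_series = {}
            for sid, o in oriented.items():
                seg = apply_calibration(o, cal,
                                        heading_window_s=config.calibration.heading_window_s)
                segment_series[model.sensor_map[sid]] = seg
            posture = reconstruct_posture(segment_series, model,
                                          anchor=config.kinematics.anchor_policy,
                                          cfg=config.kinematics)
            events = detect(posture, config.thresholds)
            if task == "swap":
                features["SWAP4"] = swap4_features(events, rec.subject_id)
                features["SWAP82"] = swap82_features(events, posture, config.features,
                                                     rec.subject_id)
            else:
                features["TUG6"] = tug6_features(events, rec.subject_id)
            manifest["stages"][task] = "ok"
        except MobikitError as exc:
            manifest["stages"][task] = f"failed at {type(exc).__name__}: {exc}"
            log.warning("subject %s task %s failed: %s", rec.subject_id, task, exc)
            raise
    return features, manifest


def run_study(datasets: Dict[str, Dataset], base_seed: int = 0) -> dict:
    """Grid evaluation + aggregation for each input set of a labelled cohort.

    Returns, per input set: the 18-row LOOCV grid, the marginal means
    over each hyperparameter axis, and a summary row (grid mean of
    TPR/TNR/ACC plus MCC and Youden's J computed from the mean rates'
    implied counts with the cohort's class sizes).
    """
    report: dict = {}
    for set_name, ds in datasets.items():
        grid = grid_evaluate(ds, base_seed=base_seed)
        n_pos = int((ds.y == ds.positive_label).sum())
        n_neg = len(ds) - n_pos
        summary = metrics.marginal_means(grid, "all")[0]
        implied = metrics.counts_from_rates(summary["tpr"], summary["tnr"],
                                            max(n_pos, 1), max(n_neg, 1))
        summary["mcc"] = metrics.mcc(implied)
        summary["j"] = metrics.youden(summary["tpr"], summary["tnr"])
        report[set_name] = {
            "grid": grid,
            "by_neurons": metrics.marginal_means(grid, "neurons"),
            "by_epochs": metrics.marginal_means(grid, "epochs"),
            "by_regularisation": metrics.marginal_means(grid, "regularisation"),
            "summary": summary,
            "n_pos": n_pos,
            "n_neg": n_neg,
        }
    return report
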