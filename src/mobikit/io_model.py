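"""Readers and writers for the package's on-disk formats.

Formats (all plain text, UTF-8, '.' decimal separator):

* IMU CSV — header ``t,sensor_id,ax,ay,az,gx,gy,gz[,mx,my,mz]``; one row
  per sample, any sensor interleaving; times in seconds, accel in m/s^2,
  gyro in deg/s.
* body model JSON — ``{"total_mass": kg, "segments": [...]}`` with the
  per-segment keys of :class:`mobikit.types.Segment`.
* features CSV — ``subject_id,set_name,<feature columns...>``.
* report JSON — nested dict of metric reports.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, FormatError, ModelError
from .types import BodyModel, FeatureVector, ImuSeries, Segment, SessionRecord

REQUIRED_COLUMNS = ["t", "sensor_id", "ax", "ay", "az", "gx", "gy", "gz"]
MAG_COLUMNS = ["mx", "my", "mz"]

#: Fallback nominal sampling rate (Hz) when it cannot be inferred.
DEFAULT_RATE = 100.0


def read_imu_csv(path, subject_id: str = "", task: str = "stance",
                 label: Optional[str] = None) -> SessionRecord:
    """Read an IMU CSV file into a :class:`SessionRecord`.

    Streams are grouped by ``sensor_id`` and sorted by time; the nominal
    rate is inferred from the median inter-sample period.  Gaps larger
    than three nominal periods are flagged on the series, which is still
    loaded.
    """
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas error paths
        raise FormatError(f"{path}: cannot parse CSV ({exc})") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    has_mag = all(c in df.columns for c in MAG_COLUMNS)
    streams: Dict[str, ImuSeries] = {}
    for sensor_id, g in df.groupby("sensor_id", sort=True):
        t = g["t"].to_numpy(dtype=float)
        if np.any(np.diff(t) <= 0):
            raise DataError(f"{path}: non-monotone time for sensor {sensor_id}")
        streams[str(sensor_id)] = ImuSeries(
            sensor_id=str(sensor_id),
            t=t,
            accel=g[["ax", "ay", "az"]].to_numpy(dtype=float),
            gyro=g[["gx", "gy", "gz"]].to_numpy(dtype=float),
            mag=g[MAG_COLUMNS].to_numpy(dtype=float) if has_mag else None,
        )
    if not streams:
        raise DataError(f"{path}: no samples")
    return SessionRecord(subject_id=subject_id, task=task, streams=streams, label=label)


def write_imu_csv(record: SessionRecord, path) -> None:
    """Write a session to IMU CSV (sensors in sorted order, values verbatim)."""
    frames: List[pd.DataFrame] = []
    has_mag = all(s.mag is not None for s in record.streams.values())
    for sensor_id in sorted(record.streams):
        s = record.streams[sensor_id]
        d = {"t": s.t, "sensor_id": sensor_id,
             "ax": s.accel[:, 0], "ay": s.accel[:, 1], "az": s.accel[:, 2],
             "gx": s.gyro[:, 0], "gy": s.gyro[:, 1], "gz": s.gyro[:, 2]}
        if has_mag:
            d.update({"mx": s.mag[:, 0], "my": s.mag[:, 1], "mz": s.mag[:, 2]})
        frames.append(pd.DataFrame(d))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


_SEGMENT_KEYS = {"name", "length", "mass_fraction", "com_offset", "parent", "sensor_id",
                 "colour", "descends", "attach", "attach_offset", "flexion_sign"}


def read_body_model(path) -> BodyModel:
    """Load and validate a body-model JSON file."""
    try:
        raw = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: invalid JSON ({exc})") from exc
    return body_model_from_dict(raw)


def body_model_from_dict(raw: dict) -> BodyModel:
    if "segments" not in raw:
        raise FormatError("body model: missing 'segments'")
    segments = []
    for sd in raw["segments"]:
        unknown = set(sd) - _SEGMENT_KEYS
        if unknown:
            raise FormatError(f"body model: unknown segment keys {sorted(unknown)}")
        try:
            segments.append(Segment(**sd))
        except TypeError as exc:
            raise FormatError(f"body model: bad segment entry ({exc})") from exc
    return BodyModel(segments=segments, total_mass=float(raw.get("total_mass", 80.0)))


def write_body_model(model: BodyModel, path) -> None:
    raw = {
        "total_mass": model.total_mass,
        "segments": [
            {
                "name": s.name, "length": s.length, "mass_fraction": s.mass_fraction,
                "com_offset": s.com_offset, "parent": s.parent, "sensor_id": s.sensor_id,
                "colour": s.colour, "descends": s.descends, "attach": s.attach,
                "attach_offset": list(map(float, s.attach_offset)),
                "flexion_sign": s.flexion_sign,
            }
            for s in model.segments
        ],
    }
    Path(path).write_text(json.dumps(raw, indent=2))


def default_body_model() -> BodyModel:
    """The packaged six-segment model: pelvis (L5), trunk (C7-TH1), thighs, shanks."""
    with resources.files("mobikit.data").joinpath("body_model_default.json").open() as fh:
        return body_model_from_dict(json.load(fh))


def write_features_csv(features: Sequence[FeatureVector], path) -> None:
    """Write feature vectors to CSV with a deterministic column order.

    Column order is ``subject_id,set_name`` followed by the feature names
    of the first vector; all vectors must share the same feature names.
    """
    if not features:
        pd.DataFrame(columns=["subject_id", "set_name"]).to_csv(path, index=False)
        return
    keys = list(features[0].values)
    rows = []
    for fv in features:
        if list(fv.values) != keys:
            raise DataError("feature vectors have inconsistent feature names")
        rows.append({"subject_id": fv.subject_id, "set_name": fv.set_name, **fv.values})
    pd.DataFrame(rows, columns=["subject_id", "set_name"] + keys).to_csv(
        path, index=False)


def read_features_csv(path) -> List[FeatureVector]:
    df = pd.read_csv(path)
    for col in ("subject_id", "set_name"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col}")
    keys = [c for c in df.columns if c not in ("subject_id", "set_name")]
    return [
        FeatureVector(str(r["subject_id"]), str(r["set_name"]),
                      {k: float(r[k]) for k in keys})
        for _, r in df.iterrows()
    ]


def write_report_json(report: dict, path) -> None:
    Path(path).write_text(json.dumps(_jsonable(report), indent=2))


def read_report_json(path) -> dict:
    return json.loads(Path(path).read_text())


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
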