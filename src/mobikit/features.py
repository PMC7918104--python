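"""Feature extraction for the SWAP 4, SWAP 82, and TUG 6 feature sets.

* SWAP 4 — four phase durations of the chair-to-chair transfer.
* SWAP 82 — the durations plus, per action window (raising / between /
  sitting): peak anterior-posterior and lateral inclination of the two
  trunk sensors' segments, and min/max inclination plus mean/max angular
  speed for every modelled segment.  With the six-segment model and
  three action windows this enumeration yields 84 features (the count is
  asserted so configuration changes are caught).
* TUG 6 — the six phase durations of the Timed Up and Go.

Inclination is the angle between the segment's anatomical up axis and
the world vertical; A-P and lateral components are the signed pitch and
roll of the intrinsic yaw-pitch-roll decomposition (forward lean and
left lean positive).  Angular speed is the norm of the segment angular
velocity.  All angles in degrees, speeds in deg/s, durations in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from . import quat
from .errors import CapabilityError, SegmentationError
from .segmentation import PhaseEvents, TUG_PHASES, _inclination_deg, _speed_dps
from .types import FeatureVector, PostureSeries

#: Action windows used for the SWAP 82 per-segment statistics.
SWAP_ACTIONS = ("raising", "between", "sitting")


@dataclass
class FeatureConfig:
    """SWAP 82 enumeration settings."""

    ap_segments: Tuple[str, str] = ("pelvis", "trunk")  # the trunk / head sensors
    ap_actions: Tuple[str, ...] = ("raising", "sitting")
    actions: Tuple[str, ...] = SWAP_ACTIONS


def swap4_features(events: PhaseEvents, subject_id: str = "") -> FeatureVector:
    """Four durations: total, raising, sitting, and the time in between."""
    b = events.boundaries
    vals = {
        "total_duration_s": b["sit_end"] - b["raise_start"],
        "raising_duration_s": b["raise_end"] - b["raise_start"],
        "sitting_duration_s": b["sit_end"] - b["sit_start"],
        "between_duration_s": b["sit_start"] - b["raise_end"],
    }
    return FeatureVector(subject_id, "SWAP4", vals)


def tug6_features(events: PhaseEvents, subject_id: str = "") -> FeatureVector:
    """Durations of the six TUG phases (their sum is the total test time)."""
    b = events.boundaries
    edges = [b[n] for n in ("raise_start", "raise_end", "turn1_start", "turn1_end",
                            "turn2_start", "sit_start", "sit_end")]
    vals = {f"{name}_s": float(e1 - e0)
            for name, e0, e1 in zip(TUG_PHASES, edges[:-1], edges[1:])}
    return FeatureVector(subject_id, "TUG6", vals)


def _window_mask(t: np.ndarray, t0: float, t1: float) -> np.ndarray:
    mask = (t >= t0 - 1e-9) & (t <= t1 + 1e-9)
    if not np.any(mask):
        raise SegmentationError(f"empty action window [{t0}, {t1}]")
    return mask


def swap82_features(events: PhaseEvents, posture: PostureSeries,
                    cfg: Optional[FeatureConfig] = None,
                    subject_id: str = "") -> FeatureVector:
    """SWAP 4 durations plus inclination/angular-speed statistics.

    Per configured trunk/head segment and A-P action: peak signed A-P
    inclination and peak absolute lateral inclination.  Per segment and
    action window: min/max inclination and mean/max angular speed.
    """
    cfg = cfg or FeatureConfig()
    model = posture.model
    b = events.boundaries
    windows = {
        "raising": (b["raise_start"], b["raise_end"]),
        "between": (b["raise_end"], b["sit_start"]),
        "sitting": (b["sit_start"], b["sit_end"]),
    }
    t = posture.t
    vals = dict(swap4_features(events, subject_id).values)
    seg_names = [s.name for s in model.segments]
    for name in cfg.ap_segments:
        if name not in posture.seg_q:
            raise CapabilityError(f"segment {name} not tracked; cannot compute SWAP 82")
    euler = {n: quat.to_euler_zyx(quat.enforce_continuity(posture.seg_q[n]), degrees=True)
             for n in cfg.ap_segments}
    for name in cfg.ap_segments:
        for action in cfg.ap_actions:
            mask = _window_mask(t, *windows[action])
            vals[f"max_ap_incl_deg_{name}_{action}"] = float(euler[name][mask, 1].max())
            vals[f"max_lat_incl_deg_{name}_{action}"] = float(
                np.abs(euler[name][mask, 2]).max())
    for name in seg_names:
        if name not in posture.seg_q:
            raise CapabilityError(f"segment {name} not tracked; cannot compute SWAP 82")
        incl = _inclination_deg(posture.seg_q[name])
        speed = _speed_dps(t, posture.seg_q[name])
        for action in cfg.actions:
            mask = _window_mask(t, *windows[action])
            vals[f"min_incl_deg_{name}_{action}"] = float(incl[mask].min())
            vals[f"max_incl_deg_{name}_{action}"] = float(incl[mask].max())
            vals[f"mean_speed_dps_{name}_{action}"] = float(speed[mask].mean())
            vals[f"max_speed_dps_{name}_{action}"] = float(speed[mask].max())
    expected = (4 + len(cfg.ap_segments) * len(cfg.ap_actions) * 2
                + len(seg_names) * len(cfg.actions) * 4)
    assert len(vals) == expected, f"SWAP82 enumeration produced {len(vals)} != {expected}"
    return FeatureVector(subject_id, "SWAP82", vals)
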