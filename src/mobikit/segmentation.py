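"""Phase segmentation of the SWAP and TUG tasks.

Both detectors are threshold-driven state machines over segment
rotations and angular speeds: rising from a chair is entered when the
trunk pitches forward faster and farther than the configured thresholds
and is confirmed when the thighs return near vertical; sitting down is
the mirror image.  TUG turns are episodes of high trunk yaw rate.
Detected boundaries are refined to the nearest movement onset/offset
(where the relevant angular speeds drop below a small epsilon), which
pins them to the true phase edges independently of threshold crossings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
from scipy.signal import butter, filtfilt

from . import quat
from .errors import InputError, SegmentationError
from .types import PostureSeries

DEG = np.pi / 180.0

SWAP_BOUNDARIES = ("raise_start", "raise_end", "sit_start", "sit_end")
TUG_BOUNDARIES = ("raise_start", "raise_end", "turn1_start", "turn1_end",
                  "turn2_start", "sit_start", "sit_end")
TUG_PHASES = ("sit_to_stand", "walk_out", "turn_first", "walk_back",
              "turn_second", "stand_to_sit")


@dataclass
class Thresholds:
    """State-machine thresholds (all positive; angles deg, speeds deg/s)."""

    trunk_pitch_deg: float = 15.0
    trunk_speed_dps: float = 20.0
    thigh_stand_deg: float = 20.0   # thigh inclination below this = standing
    thigh_sit_deg: float = 45.0     # thigh inclination crossing this = sitting down
    thigh_seated_deg: float = 70.0
    yaw_rate_dps: float = 30.0      # TUG turn detection
    debounce_s: float = 0.3
    onset_eps_dps: float = 2.0      # movement-onset refinement threshold
    max_transition_s: float = 6.0
    smooth_hz: float = 8.0

    def __post_init__(self) -> None:
        for name, v in self.__dict__.items():
            if v <= 0:
                raise InputError(f"threshold {name} must be > 0")


@dataclass
class PhaseEvents:
    """Ordered, named phase boundaries (seconds) of one task recording."""

    task: str
    boundaries: Dict[str, float]

    def __post_init__(self) -> None:
        names = SWAP_BOUNDARIES if self.task == "swap" else TUG_BOUNDARIES
        vals = [self.boundaries[n] for n in names]
        if any(later <= earlier for later, earlier in zip(vals[1:], vals[:-1])):
            raise SegmentationError(f"{self.task}: boundaries out of order: {self.boundaries}")

    def __getitem__(self, name: str) -> float:
        return self.boundaries[name]


def _signals(posture: PostureSeries, th: Thresholds):
    """Smoothed trunk pitch / thigh inclination / angular speeds."""
    t = posture.t
    rate = posture.rate
    model = posture.model
    # prefer the upper-trunk sensor's segment (it carries the full forward
    # lean); fall back to the root for reduced models
    trunk_name = "trunk" if "trunk" in model else model.root.name
    q_trunk = posture.seg_q[trunk_name]
    pitch = quat.to_euler_zyx(q_trunk, degrees=True)[:, 1]
    thighs = [s.name for s in model.segments if s.name.startswith("thigh")]
    if thighs:
        incl = np.mean([_inclination_deg(posture.seg_q[n]) for n in thighs], axis=0)
        thigh_speed = np.max([_speed_dps(t, posture.seg_q[n]) for n in thighs], axis=0)
    else:  # single-segment model: the trunk plays both roles
        incl = _inclination_deg(q_trunk)
        thigh_speed = _speed_dps(t, q_trunk)
    trunk_speed = _speed_dps(t, q_trunk)
    yaw = np.unwrap(quat.yaw_of(quat.enforce_continuity(q_trunk))) / DEG
    yaw_rate = np.gradient(yaw, t)

    def smooth(x):
        if len(x) > 15 and th.smooth_hz < rate / 2:
            b, a = butter(2, th.smooth_hz / (rate / 2))
            return filtfilt(b, a, x)
        return x

    return {
        "t": t,
        "pitch": smooth(pitch),
        "pitch_rate": smooth(np.gradient(pitch, t)),
        "thigh_incl": smooth(incl),
        "trunk_speed": smooth(trunk_speed),
        "thigh_speed": smooth(thigh_speed),
        "yaw_rate": smooth(yaw_rate),
        "rate": rate,
    }


def _inclination_deg(q: np.ndarray) -> np.ndarray:
    up = quat.rotate(q, np.array([0.0, 0.0, 1.0]))
    return np.degrees(np.arccos(np.clip(up[:, 2], -1.0, 1.0)))


def _speed_dps(t: np.ndarray, q: np.ndarray) -> np.ndarray:
    return np.linalg.norm(quat.angular_velocity_world(t, q), axis=1) / DEG


def _refine_back(activity: np.ndarray, i: int, eps: float,
                 max_steps: int = 10 ** 9) -> int:
    """Walk backward from i to the last quiet sample (movement onset).

    If no sample falls below eps within max_steps, use the quietest one:
    phase edges are local minima of angular activity.
    """
    lo = max(0, i - max_steps)
    seg = activity[lo:i + 1]
    quiet = np.flatnonzero(seg <= eps)
    return lo + int(quiet[-1]) if len(quiet) else lo + int(np.argmin(seg))


def _refine_fwd(activity: np.ndarray, i: int, eps: float,
                max_steps: int = 10 ** 9) -> int:
    """Forward counterpart of :func:`_refine_back`."""
    hi = min(len(activity) - 1, i + max_steps)
    seg = activity[i:hi + 1]
    quiet = np.flatnonzero(seg <= eps)
    return i + int(quiet[0]) if len(quiet) else i + int(np.argmin(seg))


def _find_raise(sig: dict, th: Thresholds, start_idx: int = 0):
    """(raise_start_idx, raise_end_idx) of the first sit-to-stand after start_idx."""
    t = sig["t"]
    rate = sig["rate"]
    debounce = max(1, int(round(th.debounce_s * rate)))
    cond = (sig["pitch"] > th.trunk_pitch_deg) & (sig["pitch_rate"] > th.trunk_speed_dps)
    cond[:start_idx] = False
    idx = np.flatnonzero(cond)
    max_tr = int(round(th.max_transition_s * rate))
    k = 0
    while k < len(idx):
        i = idx[k]
        # debounce: the forward-lean condition must persist
        if not np.all(sig["pitch"][i:i + debounce] > th.trunk_pitch_deg):
            k += 1
            continue
        # confirm: the thighs must come up to standing within the window
        window = sig["thigh_incl"][i:i + max_tr]
        below = np.flatnonzero(window < th.thigh_stand_deg)
        if len(below) == 0:
            k += 1
            continue
        j = i + below[0]
        activity = np.maximum(sig["trunk_speed"], sig["thigh_speed"])
        i0 = _refine_back(activity, i, th.onset_eps_dps, int(2.0 * rate))
        # raise end: the thighs are most vertical exactly when the rise
        # completes, even if walking follows immediately
        win = sig["thigh_incl"][j:j + int(1.5 * rate)]
        j1 = j + int(np.argmin(win))
        return i0, j1
    raise SegmentationError("no raising event detected")


def _find_sit(sig: dict, th: Thresholds, after_idx: int):
    """(sit_start_idx, sit_end_idx) of the stand-to-sit after after_idx.

    A candidate is a rising crossing of the thigh inclination through the
    sitting threshold; it is accepted only if the thighs reach the seated
    angle within the transition window and the trunk leans forward during
    the descent (which rejects deep-crouch walking).
    """
    rate = sig["rate"]
    max_tr = int(round(th.max_transition_s * rate))
    incl = sig["thigh_incl"]
    crossings = np.flatnonzero((incl[1:] > th.thigh_sit_deg)
                               & (incl[:-1] <= th.thigh_sit_deg)) + 1
    crossings = crossings[crossings > after_idx]
    if len(crossings) == 0:
        raise SegmentationError("no sitting event detected")
    activity = np.maximum(sig["trunk_speed"], sig["thigh_speed"])
    for i in crossings:
        seated = np.flatnonzero(incl[i:i + max_tr] > th.thigh_seated_deg)
        if len(seated) == 0:
            continue
        j = i + seated[0]
        if np.min(incl[i:j + 1]) < th.thigh_stand_deg:
            continue  # thighs returned to standing mid-way: not one descent
        # sit onset: the thighs leave their most-vertical plateau.  Locate
        # the end of the plateau first (this cannot fall in the preceding
        # walk or turn; the 3-degree band absorbs fusion jitter during a
        # turn), then refine to the local movement onset.
        win_lo = max(0, i - int(2.5 * rate))
        incl_win = incl[win_lo:i + 1]
        flat = np.flatnonzero(incl_win <= incl_win.min() + 3.0)
        i_flat = win_lo + int(flat[-1])
        i0 = _refine_back(activity, i_flat, th.onset_eps_dps, int(0.5 * rate))
        if np.max(sig["pitch"][i0:j + 1]) <= th.trunk_pitch_deg:
            continue  # no forward trunk lean over the descent: not a sit
        j1 = _refine_fwd(activity, j, th.onset_eps_dps, int(1.5 * rate))
        return i0, j1
    raise SegmentationError("sitting not completed (thighs never reach seated)")


def detect_swap_phases(posture: PostureSeries,
                       th: Optional[Thresholds] = None) -> PhaseEvents:
    """Boundaries of the chair-to-chair transfer: rise, transfer, sit."""
    th = th or Thresholds()
    sig = _signals(posture, th)
    t = sig["t"]
    r0, r1 = _find_raise(sig, th)
    s0, s1 = _find_sit(sig, th, after_idx=r1 + 1)
    return PhaseEvents("swap", {
        "raise_start": float(t[r0]), "raise_end": float(t[r1]),
        "sit_start": float(t[s0]), "sit_end": float(t[s1]),
    })


def _yaw_episodes(sig: dict, th: Thresholds, i_from: int, i_to: int) -> List[tuple]:
    """Contiguous |yaw rate| > threshold episodes, merged across short gaps."""
    rate = sig["rate"]
    active = np.abs(sig["yaw_rate"]) > th.yaw_rate_dps
    active[:i_from] = False
    active[i_to:] = False
    idx = np.flatnonzero(active)
    if len(idx) == 0:
        return []
    gaps = np.flatnonzero(np.diff(idx) > int(0.3 * rate))
    starts = np.concatenate([[0], gaps + 1])
    ends = np.concatenate([gaps, [len(idx) - 1]])
    return [(int(idx[a]), int(idx[b])) for a, b in zip(starts, ends)]


def detect_tug_phases(posture: PostureSeries,
                      th: Optional[Thresholds] = None) -> PhaseEvents:
    """Boundaries of the six TUG phases.

    Sit-to-stand and stand-to-sit use the same machine as SWAP; the two
    180-degree turns are trunk yaw-rate episodes; the walks are what lies
    between.  Missing turns raise a segmentation error naming the phase.
    """
    th = th or Thresholds()
    sig = _signals(posture, th)
    t = sig["t"]
    yaw_eps = 2.0  # deg/s, yaw-rate onset refinement
    r0, r1 = _find_raise(sig, th)
    s0, s1 = _find_sit(sig, th, after_idx=r1 + 1)
    episodes = _yaw_episodes(sig, th, r1, s0 + 1)
    # ignore small heading adjustments: a turn must exceed ~60 degrees
    turns = []
    for a, b in episodes:
        sweep = abs(np.trapezoid(sig["yaw_rate"][a:b + 1], t[a:b + 1]))
        if sweep > 60.0:
            turns.append((a, b))
    if len(turns) == 0:
        raise SegmentationError("no walking/turning found: first turn missing")
    if len(turns) == 1:
        raise SegmentationError("second turn missing")
    ay = np.abs(sig["yaw_rate"])
    w = int(1.5 * sig["rate"])
    t1a = _refine_back(ay, turns[0][0], yaw_eps, w)
    t1b = _refine_fwd(ay, turns[0][1], yaw_eps, w)
    t2a = _refine_back(ay, turns[-1][0], yaw_eps, w)
    return PhaseEvents("tug", {
        "raise_start": float(t[r0]), "raise_end": float(t[r1]),
        "turn1_start": float(t[t1a]), "turn1_end": float(t[t1b]),
        "turn2_start": float(t[t2a]), "sit_start": float(t[s0]),
        "sit_end": float(t[s1]),
    })
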