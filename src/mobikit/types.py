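"""Core domain containers: IMU streams, body model, orientations, postures.

Numeric storage is ndarray-based (one array per channel) rather than
per-sample objects; the sample/frame dataclasses are lightweight views
used at API boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np

from . import quat
from .errors import DataError, ModelError

GRAVITY = 9.81  # m/s^2

#: A gap larger than this multiple of the nominal period is flagged.
GAP_FACTOR = 3.0


@dataclass
class ImuSample:
    """One timestamped IMU reading (accel m/s^2, gyro deg/s, mag arbitrary)."""

    t: float
    accel: np.ndarray
    gyro: np.ndarray
    mag: Optional[np.ndarray] = None


@dataclass
class ImuSeries:
    """Time series of IMU samples for one sensor.

    ``accel`` in m/s^2 (a level, static sensor reads +GRAVITY on its z
    axis), ``gyro`` in deg/s, ``mag`` optional and in arbitrary units.
    """

    sensor_id: str
    t: np.ndarray
    accel: np.ndarray
    gyro: np.ndarray
    mag: Optional[np.ndarray] = None
    rate: float = 0.0
    gap_flags: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        if self.mag is not None:
            self.mag = np.asarray(self.mag, dtype=float)
        if len(self.t) < 2:
            raise DataError(f"sensor {self.sensor_id}: need at least 2 samples")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            raise DataError(f"sensor {self.sensor_id}: time not strictly increasing")
        if not (np.all(np.isfinite(self.accel)) and np.all(np.isfinite(self.gyro))):
            raise DataError(f"sensor {self.sensor_id}: non-finite accel/gyro")
        if not self.rate:
            self.rate = 1.0 / float(np.median(dt))
        if self.gap_flags is None:
            self.gap_flags = np.concatenate([[False], dt > GAP_FACTOR / self.rate])

    def __len__(self) -> int:
        return len(self.t)

    @property
    def has_gaps(self) -> bool:
        return bool(np.any(self.gap_flags))

    @property
    def samples(self) -> List[ImuSample]:
        mag = self.mag
        return [
            ImuSample(self.t[i], self.accel[i], self.gyro[i], None if mag is None else mag[i])
            for i in range(len(self.t))
        ]


CALIBRATION_TASKS = ("calibration_start", "calibration_end")
KNOWN_TASKS = ("swap", "tug", "stance") + CALIBRATION_TASKS


@dataclass
class SessionRecord:
    """One recording session: a task and one stream per sensor."""

    subject_id: str
    task: str
    streams: Dict[str, ImuSeries]
    label: Optional[str] = None  # "faller" / "non-faller"

    def common_window(self) -> tuple:
        t0 = max(s.t[0] for s in self.streams.values())
        t1 = min(s.t[-1] for s in self.streams.values())
        return t0, t1


@dataclass
class Segment:
    """Rigid body segment.

    The segment frame is anatomical: +Z up, +X forward, +Y left when the
    subject stands upright facing world +X.  ``descends`` marks segments
    whose proximal->distal axis points down in that pose (legs), so the
    axis in the local frame is -Z instead of +Z.  ``flexion_sign`` is the
    expected sign of the sagittal (pitch) rotation during a forward
    lean-and-squat, used to disambiguate the calibration pitch axis:
    trunk and shank tip forward (+1), thighs flex backward (-1).
    """

    name: str
    length: float
    mass_fraction: float
    com_offset: float = 0.5
    parent: Optional[str] = None  # None -> root
    sensor_id: Optional[str] = None
    colour: str = "grey"
    descends: bool = False
    attach: str = "distal"  # attachment point on the parent: distal|proximal
    attach_offset: np.ndarray = field(default_factory=lambda: np.zeros(3))
    flexion_sign: float = 1.0

    def __post_init__(self) -> None:
        self.attach_offset = np.asarray(self.attach_offset, dtype=float)
        if self.length <= 0:
            raise ModelError(f"segment {self.name}: length must be > 0")
        if not 0.0 <= self.com_offset <= 1.0:
            raise ModelError(f"segment {self.name}: com_offset outside [0, 1]")
        if not 0.0 <= self.mass_fraction < 1.0:
            raise ModelError(f"segment {self.name}: mass_fraction outside [0, 1)")
        if self.attach not in ("distal", "proximal"):
            raise ModelError(f"segment {self.name}: attach must be distal|proximal")

    @property
    def axis_local(self) -> np.ndarray:
        """Unit vector proximal -> distal in the segment frame."""
        return np.array([0.0, 0.0, -1.0 if self.descends else 1.0])


@dataclass
class BodyModel:
    """Tree of rigid segments rooted at the pelvis."""

    segments: List[Segment]
    total_mass: float = 80.0

    def __post_init__(self) -> None:
        names = [s.name for s in self.segments]
        if len(set(names)) != len(names):
            raise ModelError("duplicate segment names")
        by_name = {s.name: s for s in self.segments}
        roots = [s for s in self.segments if s.parent is None or s.parent == "ground"]
        if len(roots) != 1:
            raise ModelError(f"expected exactly one root segment, found {len(roots)}")
        for s in self.segments:
            if s.parent not in (None, "ground") and s.parent not in by_name:
                raise ModelError(f"segment {s.name}: unknown parent {s.parent!r}")
        # cycle check by walking to the root from every segment
        for s in self.segments:
            seen = set()
            cur = s
            while cur.parent not in (None, "ground"):
                if cur.name in seen:
                    raise ModelError(f"cyclic topology through segment {cur.name}")
                seen.add(cur.name)
                cur = by_name[cur.parent]
        total_fraction = sum(s.mass_fraction for s in self.segments)
        if total_fraction > 1.0 + 1e-9:
            raise ModelError(f"mass fractions sum to {total_fraction:.3f} > 1")
        sensors = [s.sensor_id for s in self.segments if s.sensor_id]
        if len(set(sensors)) != len(sensors):
            raise ModelError("a sensor_id is assigned to more than one segment")

    @property
    def root(self) -> Segment:
        return next(s for s in self.segments if s.parent in (None, "ground"))

    def __getitem__(self, name: str) -> Segment:
        for s in self.segments:
            if s.name == name:
                return s
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(s.name == name for s in self.segments)

    def children(self, name: str) -> List[Segment]:
        return [s for s in self.segments if s.parent == name]

    def topological_order(self) -> List[Segment]:
        order: List[Segment] = [self.root]
        i = 0
        while i < len(order):
            order.extend(self.children(order[i].name))
            i += 1
        return order

    @property
    def sensor_map(self) -> Dict[str, str]:
        """sensor_id -> segment name."""
        return {s.sensor_id: s.name for s in self.segments if s.sensor_id}


@dataclass
class OrientationSeries:
    """Per-sample orientation (frame -> world unit quaternions) for one sensor/segment."""

    sensor_id: str
    t: np.ndarray
    q: np.ndarray  # (N, 4) scalar-first

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.q = np.asarray(self.q, dtype=float)
        if self.q.shape != (len(self.t), 4):
            raise DataError("orientation series shape mismatch")

    def __len__(self) -> int:
        return len(self.t)

    def resampled(self, t_new: np.ndarray) -> "OrientationSeries":
        return OrientationSeries(self.sensor_id, np.asarray(t_new, float),
                                 quat.slerp_series(self.t, self.q, t_new))


@dataclass
class PostureFrame:
    """Single reconstructed frame: per-segment orientation + world joint positions."""

    t: float
    seg_q: Dict[str, np.ndarray]
    joints: Dict[str, Dict[str, np.ndarray]]  # name -> {"proximal": xyz, "distal": xyz}
    com: Optional[np.ndarray] = None
    root_translation: Optional[np.ndarray] = None


@dataclass
class PostureSeries:
    """Reconstructed kinematics: per-segment orientation series on a common clock."""

    model: BodyModel
    t: np.ndarray
    seg_q: Dict[str, np.ndarray]        # segment name -> (N, 4)
    root_pos: Optional[np.ndarray] = None  # (N, 3) world position of the root proximal joint
    joints: Optional[Dict[str, Dict[str, np.ndarray]]] = None  # filled by forward kinematics
    com: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        if np.any(np.diff(self.t) <= 0):
            raise DataError("posture series time not strictly increasing")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.t)))

    def frame(self, i: int) -> PostureFrame:
        joints = {}
        if self.joints is not None:
            joints = {k: {kk: vv[i] for kk, vv in v.items()} for k, v in self.joints.items()}
        return PostureFrame(
            t=float(self.t[i]),
            seg_q={k: v[i] for k, v in self.seg_q.items()},
            joints=joints,
            com=None if self.com is None else self.com[i],
            root_translation=None if self.root_pos is None else self.root_pos[i],
        )


@dataclass
class FootForces:
    """Vertical ground reaction force per foot (N) and support state."""

    t: np.ndarray
    left: np.ndarray
    right: np.ndarray
    support: np.ndarray  # array of {"double","left","right"}
    clamped: np.ndarray  # frames where the COM projection fell outside the feet


@dataclass
class FeatureVector:
    """Named per-subject features for one feature set (SWAP4 / SWAP82 / TUG6)."""

    subject_id: str
    set_name: str
    values: "dict[str, float]"

    def as_array(self, order: Optional[Sequence[str]] = None) -> np.ndarray:
        keys = list(self.values) if order is None else list(order)
        return np.array([self.values[k] for k in keys], dtype=float)
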