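"""Exception hierarchy for the mobility-analysis pipeline."""


class MobikitError(Exception):
    """Base class for all package errors."""


class FormatError(MobikitError):
    """A file does not match the documented on-disk format."""


class DataError(MobikitError):
    """Well-formed file, but the data violate an invariant (e.g. time order)."""


class ModelError(MobikitError):
    """Invalid body-model definition (cycle, unknown parent, bad masses)."""


class FusionError(MobikitError):
    """Orientation estimation cannot run (e.g. series too short)."""


class CalibrationError(MobikitError):
    """Sensor-to-segment calibration failed or is unavailable."""


class UnstableStanceError(CalibrationError):
    """Gravity direction too dispersed during the upright-stance window."""


class AmbiguousMovementError(CalibrationError):
    """Lean-and-squat window has no single dominant rotation axis."""


class MappingError(MobikitError):
    """A sensor or segment referenced by one stage is missing in another."""


class AlignmentError(MobikitError):
    """Sensor streams share no common time window."""


class CapabilityError(MobikitError):
    """The sensor configuration cannot support the requested computation."""


class SegmentationError(MobikitError):
    """Phase segmentation failed (missing event, disordered boundaries)."""


class SpecError(MobikitError):
    """Invalid classifier or feature-set specification."""


class InputError(MobikitError):
    """Out-of-range or mismatched numeric input."""
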