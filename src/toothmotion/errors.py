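"""Exception hierarchy for toothmotion."""


class ToothMotionError(Exception):
    """Base class for all toothmotion errors."""


class InvalidTransformError(ToothMotionError):
    """Matrix is not a proper rotation (non-orthogonal or reflecting)."""


class DegenerateGeometryError(ToothMotionError):
    """Point configuration is too degenerate for the requested fit
    (fewer than the minimum number of points, collinear, or coincident)."""


class DegenerateRotationError(ToothMotionError):
    """Rotation angle is below the degeneracy threshold: the helical-axis
    position is undefined and the pure-translation path must be used."""


class IllConditionedPointError(ToothMotionError):
    """A reference point lies on or too close to the helical axis."""


class InconsistentAxisError(ToothMotionError):
    """The supplied direction is not the rotation axis of the transform."""


class PointCloudFormatError(ToothMotionError):
    """A point-cloud file could not be parsed."""


class ConfigError(ToothMotionError):
    """An analysis configuration is invalid."""
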