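"""Exception types shared across the pipeline stages."""


class RingcurvError(Exception):
    """Base class for all pipeline errors."""


class DegenerateGeometryError(RingcurvError):
    """Foreground has no distinguished plane (e.g. a filled sphere)."""


class UnthresholdableError(RingcurvError):
    """Image cannot be thresholded (constant intensity)."""


class NoRingError(RingcurvError):
    """Skeleton contains no closed cycle."""


class DegenerateTripleError(RingcurvError):
    """Coincident points passed to the three-point circle fit."""


class OffsetTooLargeError(RingcurvError):
    """Curvature arc offset exceeds half the cycle perimeter."""


class NotCompressedRingError(RingcurvError):
    """Curvature profile is not a two-flat / two-cap topology."""


class InsufficientFramesError(RingcurvError):
    """Too few frames for a regression-based rate estimate."""


class NoBundlesError(RingcurvError):
    """No bundle records available for the requested statistic."""


class NoExpulsionError(RingcurvError):
    """Time-lapse contains no frame with detected bundles."""


class IntensityError(RingcurvError):
    """Invalid intensity bookkeeping input (e.g. non-positive denominator)."""


class UnfittableProfileError(RingcurvError):
    """Gaussian fit of a line profile failed or is out of range."""
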