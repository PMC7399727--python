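"""Exception hierarchy for the rkt package."""


class RktError(Exception):
    """Base class for all rkt-specific errors."""


class SchemaError(RktError):
    """A table is missing required columns or violates the trial schema."""


class MonotonicityError(RktError):
    """Torque within a sweep is not monotone in the required direction."""


class CalibrationError(RktError):
    """No curve in the generator family reproduces the requested features."""


class FitError(RktError):
    """Cubic fitting failed (too few points or rank-deficient design)."""


class TurningPointError(RktError):
    """The unity-slope criterion has no admissible root on a curve side."""


class DesignError(RktError):
    """The subject/knee/day layout is unusable for the requested analysis."""
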