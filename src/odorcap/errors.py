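"""Exception hierarchy for odorcap."""


class OdorcapError(Exception):
    """Base class for all odorcap errors."""


class ConfigurationError(OdorcapError):
    """Invalid model kind, parameter, or run configuration."""


class InfeasibleDesignError(OdorcapError):
    """A mixture design that cannot be drawn from the primary pool (2N - O > C)."""


class InvalidMixtureError(OdorcapError):
    """A mixture with no components, or otherwise malformed."""


class DegenerateMixtureError(OdorcapError):
    """A ring mixture whose component vectors sum to (numerically) zero."""


class ProtocolError(OdorcapError):
    """A model routed through a discrimination protocol it does not support."""


class CalibrationError(OdorcapError):
    """Noise calibration failed to converge to the requested tolerance."""


class EstimationError(OdorcapError):
    """A Monte-Carlo search (capacity, critical size) exhausted its bounds."""


class NoCriticalDistanceError(OdorcapError):
    """A discriminability curve that never reaches the criterion level."""
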