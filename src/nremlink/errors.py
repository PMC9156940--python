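"""Exception hierarchy shared across modules."""


class NremlinkError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(NremlinkError, ValueError):
    """An argument violates a documented precondition."""


class InsufficientDataError(NremlinkError):
    """Not enough data to compute the requested quantity."""


class CalibrationError(NremlinkError):
    """Automatic threshold calibration failed (e.g. degenerate features)."""


class DegenerateBaselineError(NremlinkError):
    """Baseline value is zero; dF/F undefined."""


class InvalidStateError(NremlinkError):
    """Operation called on an object in the wrong state (e.g. untrained model)."""


class TrainingError(NremlinkError):
    """Model training failed (non-finite loss)."""


class NoOverlapError(NremlinkError):
    """Join produced no rows."""


class InvalidReferenceError(NremlinkError):
    """Reference quantity is degenerate (e.g. zero reference distance)."""


class UndefinedRatioError(NremlinkError):
    """Ratio undefined because the denominator is zero."""


class InsufficientVarianceError(NremlinkError):
    """Input values are (nearly) identical; fit is degenerate."""
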