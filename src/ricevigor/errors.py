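"""Exception hierarchy shared across the pipeline."""


class VigorError(Exception):
    """Base class for all ricevigor errors."""


class ValidationError(VigorError, ValueError):
    """An argument violates a documented precondition or invariant."""


class DecodeError(VigorError, IOError):
    """An image file could not be read or decoded."""


class ParseError(VigorError, ValueError):
    """A trait table could not be parsed; carries row/column coordinates."""

    def __init__(self, message: str, row=None, column=None):
        super().__init__(message)
        self.row = row
        self.column = column


class CalibrationError(ValidationError):
    """Degenerate or inconsistent pixel-to-millimetre calibration."""


class IncompleteSessionError(ValidationError):
    """An imaging session is missing one or more required views."""


class TimeOrderError(ValidationError):
    """Growth observations are not strictly ordered in time."""


class DomainError(ValidationError):
    """A value lies outside the mathematical domain of an operation."""


class DegenerateStatisticError(VigorError, ValueError):
    """A statistic is undefined for the given data (zero variance etc.)."""
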