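"""Exception hierarchy for fdgki.

All package-specific failures derive from :class:`FdgkiError` so callers
(and the CLI) can distinguish domain errors from programming errors.
"""


class FdgkiError(Exception):
    """Base class for all fdgki errors."""


class FormatError(FdgkiError):
    """A file does not conform to the expected CSV/JSON dialect."""


class ValidationError(FdgkiError):
    """Input data violates a structural or physiological invariant."""


class InsufficientDataError(FdgkiError):
    """Too few frames/samples in the requested window for a fit."""


class DegenerateInputError(FdgkiError):
    """A curve is degenerate (e.g. all-zero) for the requested operation."""


class DecompositionError(FdgkiError):
    """Exponential peeling produced an inconsistent rate ordering."""


class CalibrationDomainError(FdgkiError):
    """A calibration regression was evaluated outside its valid domain."""


class CalibrationUnitsError(FdgkiError):
    """A calibration's unit binding does not match the data units."""
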