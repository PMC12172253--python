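"""Exception taxonomy shared across the pipeline.

Validation failures raise :class:`InvalidParameterError` (bad configuration
or out-of-range argument), data problems raise :class:`InsufficientDataError`
or :class:`RecordingQualityError`, and format problems on ingest raise
:class:`FormatError`.  All inherit :class:`InteropipeError` so callers can
catch pipeline errors wholesale.
"""


class InteropipeError(Exception):
    """Base class for all interopipe errors."""


class InvalidParameterError(InteropipeError, ValueError):
    """A parameter or configuration value is outside its valid range."""


class InvalidRatingError(InvalidParameterError):
    """A questionnaire/Likert response lies outside its instrument bounds."""


class InsufficientDataError(InteropipeError):
    """Too little data for the requested computation (short recording, n too small)."""


class EmptySeriesError(InsufficientDataError):
    """No events were found in a signal (e.g. no R peaks detected)."""


class RecordingQualityError(InteropipeError):
    """A recording failed quality control and must be excluded."""


class UndefinedStatisticError(InteropipeError):
    """The requested statistic is undefined for this input (zero denominator/variance)."""


class AliasingError(InteropipeError):
    """A design matrix is rank deficient (exactly collinear columns)."""

    def __init__(self, message, columns=()):
        super().__init__(message)
        self.columns = list(columns)


class FormatError(InteropipeError):
    """An input file violates the expected on-disk format or schema."""


class MissingDataError(InteropipeError):
    """A required field or timepoint is absent."""
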