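"""Exception hierarchy for the dyadsync pipeline.

Every failure mode surfaced by the pipeline derives from :class:`DyadsyncError`
so callers can catch pipeline problems without masking programming errors.
"""


class DyadsyncError(Exception):
    """Base class for all dyadsync errors."""


class ParseError(DyadsyncError):
    """A marker or metadata file could not be parsed; names the offending line."""


class IntegrityError(DyadsyncError):
    """Structural violation in an input table, e.g. duplicated (frame, marker)."""


class LabelingError(DyadsyncError):
    """A marker present in the data has no entry in the labeling map."""


class ConfigurationError(DyadsyncError):
    """An analysis or simulation configuration is inconsistent or incomplete."""


class MetadataError(DyadsyncError):
    """Dyad metadata violates its invariants (e.g. climax outside recording)."""


class DegenerateGeometryError(DyadsyncError):
    """The two interactants' mean positions coincide; no proximity axis exists."""


class InsufficientDataError(DyadsyncError):
    """Too few samples for the requested operation (e.g. < 2 for a difference)."""


class ParameterError(DyadsyncError):
    """A numeric parameter is outside its valid range (e.g. cutoff >= Nyquist)."""


class UndefinedCorrelationError(DyadsyncError):
    """Correlation is undefined because a signal segment has zero energy."""


class AlignmentError(DyadsyncError):
    """Two curves do not share a lag grid and cannot be combined."""
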