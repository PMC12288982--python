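"""Exception hierarchy.

All domain errors derive from :class:`RusfError` so callers can catch one
base class; individual types mirror the failure modes of each stage.
"""


class RusfError(ValueError):
    """Base class for all domain errors raised by this package."""


class ValidationError(RusfError):
    """Input violates a stated precondition or invariant."""


class KeyedDuplicateError(ValidationError):
    """Duplicate (subject, timepoint) key within a table."""


class EmptyAfterFilterError(RusfError):
    """Complete-case filtering removed every sample or every marker."""


class AlignmentError(RusfError):
    """Sample alignment across tables produced an empty intersection."""


class InsufficientDataError(RusfError):
    """Too few observations for the requested computation."""


class DegenerateTableError(RusfError):
    """Contingency table with a zero expected cell."""


class DegenerateLabelError(RusfError):
    """A label vector with a single class where two are required."""


class StratificationError(RusfError):
    """A stratified split left one side without both classes."""


class EmptySampleError(RusfError):
    """A sample with zero total counts where proportions are needed."""


class ConfigurationError(RusfError):
    """Inconsistent or incomplete run configuration."""


class TransferError(RusfError):
    """Cross-cohort transfer impossible (no shared features)."""


class SchemaError(RusfError):
    """A required feature column is missing from an input table."""
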