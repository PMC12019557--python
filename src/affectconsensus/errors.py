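"""Exception hierarchy for the annotation-consensus pipeline.

Every error raised on purpose by the package derives from
:class:`AffectConsensusError`, so callers can catch pipeline failures
without masking programming errors.
"""


class AffectConsensusError(Exception):
    """Base class for all errors raised by this package."""


class InvalidParameterError(AffectConsensusError, ValueError):
    """A parameter is outside its documented domain."""


class InvalidClipError(AffectConsensusError, ValueError):
    """A clip lies outside the film bounds or overlaps another clip."""


class DuplicateRecordError(AffectConsensusError):
    """The same rater x film x item combination appears twice on disk."""


class AnnotationParseError(AffectConsensusError):
    """A tabular annotation file could not be parsed.

    The message carries the offending file and, where known, line number.
    """


class EmptyInputError(AffectConsensusError):
    """An input file or record collection is empty where data is required."""


class StateError(AffectConsensusError):
    """A series is in the wrong state (raw vs z-scored) for an operation."""


class UnsupportedGapError(AffectConsensusError):
    """A missing-data gap of two or more adjacent samples was found and the
    two-neighbour imputation rule cannot be applied."""


class InsufficientRatersError(AffectConsensusError):
    """Fewer series are available than the operation's rater floor."""


class AlignmentError(AffectConsensusError):
    """Two time series or index sets that must align do not."""


class LedgerError(AffectConsensusError):
    """The exclusion ledger violates its conservation identity."""


class InfeasibleGridError(AffectConsensusError):
    """The requested assignment grid cannot satisfy its coverage constraint."""


class AliasingError(AffectConsensusError):
    """A trace's sampling rate is too low for the requested filtering."""


class InsufficientDataError(AffectConsensusError):
    """A trace is too short for the requested windowed computation."""


class OverwriteError(AffectConsensusError):
    """Refusing to overwrite existing output without the overwrite flag."""
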