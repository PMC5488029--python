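"""Exception hierarchy for venomprint.

All package errors derive from :class:`VenomprintError` so callers can catch
one base class; the CLI maps validation-type errors to exit code 2 and
runtime failures to exit code 1.
"""


class VenomprintError(Exception):
    """Base class for all venomprint errors."""


class ValidationError(VenomprintError):
    """Invalid configuration or malformed input that the user must fix."""


class TraceFormatError(ValidationError):
    """A trace file violates the documented CSV dialect (e.g. non-monotone time)."""


class DegenerateTraceError(ValidationError):
    """A trace is too short to process (fewer than 10 samples)."""


class MatrixFormatError(ValidationError):
    """A binary-matrix file contains cells outside {0, 1} or is malformed."""


class ManifestError(ValidationError):
    """Sample manifest violates its invariants (duplicate ids, gappy replicates)."""


class CalibrationError(ValidationError):
    """Ladder table unusable for sizing (fewer than 2 points, non-monotone)."""


class StandardsNotFoundError(VenomprintError):
    """No internal-standard peak found in its search window; the run must be repeated."""


class DegenerateStandardsError(VenomprintError):
    """Lower and upper internal standards coincide; no affine alignment exists."""


class UndefinedDistanceError(VenomprintError):
    """Bray-Curtis distance undefined for a pair of all-zero profiles."""


class UndefinedRateError(VenomprintError):
    """Mismatch error rate requested over zero comparisons."""


class EmptyAnalysisError(VenomprintError):
    """No polymorphic markers remain; downstream analysis is impossible."""
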