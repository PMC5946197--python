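"""Exception hierarchy for metscreen.

Every error raised by the package derives from :class:`MetscreenError`, so
callers can catch one type at pipeline boundaries while tests assert the
specific subclass.
"""


class MetscreenError(Exception):
    """Base class for all metscreen errors."""


class SchemaError(MetscreenError):
    """An input table is missing a mapped column or has an unusable header."""


class AgeOutOfRangeError(MetscreenError):
    """An age falls outside every configured age-group bin."""


class DomainError(MetscreenError, ValueError):
    """An index function received an argument outside its domain."""


class CoverageError(MetscreenError):
    """A growth-reference lookup fell outside the tabulated age range."""


class ClassificationError(MetscreenError):
    """A component rule referenced a field that is missing for a subject."""


class CriteriaConstructionError(MetscreenError):
    """A criterion set could not be built (e.g. missing percentile tables)."""


class DegenerateCohortError(MetscreenError):
    """A cohort-level statistic is undefined (zero variance, n too small)."""


class DegenerateLabelsError(MetscreenError):
    """ROC construction needs at least one positive and one negative label."""


class InsufficientDataError(MetscreenError):
    """Too few observations per class for the requested interval/test."""


class CollinearityError(MetscreenError):
    """Covariate matrix is rank deficient."""


class DegeneracyError(MetscreenError):
    """Residual variance vanished after covariate adjustment."""


class SpanTooSmallError(MetscreenError):
    """LOWESS span leaves fewer than three points per local window."""


class SpecError(MetscreenError):
    """A simulation stratum specification is invalid."""


class BoundsTooTightError(MetscreenError):
    """Truncation bounds rejected essentially every simulated draw."""


class ConfigError(MetscreenError):
    """A pipeline run configuration is invalid or references missing files."""


class PipelineError(MetscreenError):
    """A pipeline stage failed fatally."""
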