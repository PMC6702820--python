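"""Exception hierarchy.

Everything user-facing derives from :class:`QamsError` so callers (and the
CLI) can distinguish domain errors from programming errors.
"""


class QamsError(Exception):
    """Base class for all errors raised by this package."""


class SchemaError(QamsError):
    """A required column is missing or a file has the wrong layout."""


class ValidationError(QamsError):
    """Input values violate a domain invariant (negative area, rt <= 0, ...)."""


class UnknownAnalyteError(ValidationError):
    """An analyte name could not be resolved through the synonym registry."""


class FixtureLookupError(QamsError, KeyError):
    """Requested packaged table does not exist."""


class RecipeError(QamsError):
    """A dilution recipe is inconsistent (overfull flask, unknown stock)."""


class FitError(QamsError):
    """A regression cannot be fitted (too few points, zero x-variance)."""


class MissingPeakError(QamsError):
    """A required (reference or standard) peak is absent from a run."""


class AmbiguousPeakError(QamsError):
    """Two peaks compete for one analyte during retention-time assignment."""


class UndefinedFError(QamsError):
    """F statistic is 0/0: no glycosides and no aglycones detected."""
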