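"""Exception hierarchy shared across the package.

Everything derives from :class:`ScctrajError` so callers can catch the
package's failures with one except clause; the leaf classes mirror the
validation contracts of the individual stages.
"""


class ScctrajError(Exception):
    """Base class for all scctraj errors."""


class InvalidArgumentError(ScctrajError, ValueError):
    """A scalar argument violates its precondition (sign, range, enum)."""


class InsufficientDataError(ScctrajError, ValueError):
    """A series or stratum has too few observations for the operation."""


class DegenerateDesignError(ScctrajError, ValueError):
    """The design matrix (or time axis) is collinear or constant."""


class InvalidCohortError(ScctrajError, ValueError):
    """A cohort-level precondition fails (empty subgroup, n < k, ...)."""


class InvalidTableError(ScctrajError, ValueError):
    """A contingency table has a zero margin or negative cell."""


class UndefinedCorrelationError(ScctrajError, ValueError):
    """A correlation is requested on a zero-variance variable."""


class InvalidConfigError(ScctrajError, ValueError):
    """A configuration object is internally inconsistent."""


class SchemaError(ScctrajError, ValueError):
    """An input file is missing required columns."""


class IntegrityError(ScctrajError, ValueError):
    """An input file violates uniqueness/ordering constraints."""
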