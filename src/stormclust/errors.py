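"""Exception hierarchy.

All package-specific failures derive from :class:`StormClustError` so callers
can catch one base class; parameter/validation problems additionally derive
from :class:`ValueError` for ergonomic use.
"""


class StormClustError(Exception):
    """Base class for all stormclust errors."""


class FormatError(StormClustError):
    """A file does not have the structure the dialect requires."""


class ParseError(StormClustError):
    """A value in an otherwise well-formed file could not be parsed."""


class ParameterError(StormClustError, ValueError):
    """An argument violates a documented precondition."""


class ValidationError(StormClustError, ValueError):
    """A configuration or data structure violates its invariants."""


class SizeError(StormClustError):
    """A request would generate an unreasonably large simulation."""


class FeasibilityError(StormClustError):
    """A constrained sampling problem could not be satisfied."""


class FitError(StormClustError):
    """A model fit failed to converge or the data are degenerate."""


class UndefinedStatisticError(StormClustError):
    """A statistic was requested on input for which it is undefined."""
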