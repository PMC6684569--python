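"""Exception hierarchy.

All package-specific failures derive from :class:`ConnlifeError` so callers
can catch one base class at pipeline level while tests assert the precise
subtype.
"""


class ConnlifeError(Exception):
    """Base class for all connlife errors."""


class ParameterError(ConnlifeError, ValueError):
    """Invalid user-supplied parameter (out of range, wrong sign, ...)."""


class ValidationError(ConnlifeError, ValueError):
    """Inconsistent or malformed input data (shape/length mismatches, NaNs)."""


class ConfigurationError(ConnlifeError, ValueError):
    """A run configuration that cannot be satisfied (e.g. empty reference group)."""


class GenerationError(ConnlifeError, RuntimeError):
    """Synthetic-data generation failed (e.g. unrepairable covariance block)."""


class DegenerateInputError(ConnlifeError, ValueError):
    """Statistic requested on degenerate data (constant series, zero variance)."""


class UndefinedStatisticError(ConnlifeError, ArithmeticError):
    """The requested statistic is mathematically undefined for this input."""


class UndefinedMetricError(ConnlifeError, ArithmeticError):
    """A graph metric is undefined for this graph (e.g. no reachable pairs)."""
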