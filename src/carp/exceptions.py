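"""Exception hierarchy.

All package-specific errors derive from :class:`CarpError` so callers can
catch one base class; parameter/input errors additionally derive from
``ValueError`` for interoperability with generic validation code.
"""


class CarpError(Exception):
    """Base class for all errors raised by this package."""


class InvalidParameterError(CarpError, ValueError):
    """A function argument is outside its documented domain."""


class InvalidInputError(CarpError, ValueError):
    """Input data violate a structural precondition (shape, range, pairing)."""


class InsufficientDataError(CarpError):
    """Too few subjects to carry out the requested estimation."""


class DegenerateScoresError(CarpError):
    """All conditioning scores are identical; no quantile layering possible."""


class DegenerateTableError(CarpError):
    """Every layer of a 2x2xm table is uninformative (zero variance contribution)."""

    def __init__(self, message: str = "all layers degenerate", layers_used: int = 0):
        super().__init__(message)
        self.layers_used = layers_used


class UndefinedCorrelationError(CarpError):
    """A conditional correlation is undefined (zero mass or degenerate marginal)."""


class NoMaximumError(CarpError):
    """A fitted quadratic has no interior maximum on (0, 1)."""


class EnumerationBoundError(CarpError):
    """Pattern enumeration requested beyond the supported number of items."""
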