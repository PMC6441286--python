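"""Exception hierarchy.

All validation failures raise a subclass of :class:`ZassocError`, which is a
``ValueError`` so that generic callers can still catch it conventionally.
"""


class ZassocError(ValueError):
    """Base class for all package-specific errors."""


class DimensionMismatchError(ZassocError):
    """Counts matrix shape does not match the supplied label vectors."""


class DuplicateLabelError(ZassocError):
    """A row or column label vector contains duplicates."""


class InvalidEntryError(ZassocError):
    """A cell is negative, NaN or infinite."""


class EmptyTableError(ZassocError):
    """All cells are zero (total mass is zero)."""


class GroupingCoverageError(ZassocError):
    """A grouping map does not cover the axis labels exactly."""


class DegenerateMarginError(ZassocError):
    """A row or column marginal required to be positive is zero."""


class ShapeError(ZassocError):
    """Table shape is unsuitable for the requested operation."""


class UndefinedRatioError(ZassocError):
    """Error-rate ratio is undefined because P(A) = 1."""


class ContractViolationError(ZassocError):
    """Caller violated an internal pre-condition (e.g. zero row marginal)."""


class TableParseError(ZassocError):
    """A delimited table or grouping file could not be parsed."""
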