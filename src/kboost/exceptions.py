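"""Exception hierarchy.

Everything raised deliberately by this package derives from :class:`KBoostError`
so callers (and the CLI) can catch one type.
"""


class KBoostError(Exception):
    """Base class for all errors raised by kboost."""


class InvalidParameterError(KBoostError, ValueError):
    """A configuration or function parameter is outside its valid range."""


class InvalidInputError(KBoostError, ValueError):
    """Numeric input data violates a precondition (e.g. non-finite values)."""


class ShapeError(KBoostError, ValueError):
    """Array arguments have inconsistent or invalid shapes."""


class DegenerateTFError(KBoostError):
    """A TF's centered kernel has no retainable variance (e.g. constant expression)."""


class UndefinedMetricError(KBoostError):
    """A ranking metric was requested on a gold standard that cannot support it."""


class FormatError(KBoostError, ValueError):
    """A file being read violates its expected format."""


class CycleError(KBoostError):
    """A network expected to be acyclic contains a directed cycle."""
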