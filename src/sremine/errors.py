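"""Exception hierarchy.

All failures raised by this package derive from :class:`SremineError`, so
callers can catch one type at pipeline boundaries while still seeing the
specific category (bad parameter vs. malformed input vs. bad query).
"""


class SremineError(Exception):
    """Base class for all errors raised by sremine."""


class ParameterError(SremineError, ValueError):
    """A run parameter (k, R, alpha, theta, beta, window, ...) is out of range."""


class InputError(SremineError, ValueError):
    """An input file or table is malformed (duplicate rows, bad alphabet, ...)."""


class QueryError(SremineError, KeyError):
    """A lookup referenced an entity that does not exist (unknown k-mer/exon)."""


class GenerationError(SremineError, RuntimeError):
    """The synthetic-data generator could not satisfy its placement contract."""
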