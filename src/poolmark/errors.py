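"""Exception hierarchy."""


class PoolmarkError(Exception):
    """Base class for all package-specific errors."""


class ParseError(PoolmarkError):
    """A file could not be parsed into a valid object (names the offending row/column)."""


class DataError(PoolmarkError):
    """Input data violate a precondition (degenerate distribution, no mappable probes, ...)."""


class QueryError(PoolmarkError):
    """A survival query cannot be answered (gene not measured, single-group cohort, ...)."""
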