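"""Exception types shared across the package."""


class GroomstatsError(Exception):
    """Base class for all package errors."""


class ConfigurationError(GroomstatsError, ValueError):
    """A configuration value is invalid; the message names the field."""


class SchemaError(GroomstatsError, ValueError):
    """A delimited input file violates its schema; the message carries the
    offending row number where one exists."""


class MatrixFormatError(GroomstatsError, ValueError):
    """A sociometric-matrix CSV is malformed (non-square, id mismatch,
    negative entry)."""


class DataError(GroomstatsError, ValueError):
    """Structurally valid records that are jointly inconsistent, e.g.
    overlapping grooming segments for the same directed pair."""


class AssemblyError(GroomstatsError, ValueError):
    """Dyad-table assembly could not populate every predictor."""
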