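"""Exception hierarchy shared across the package."""


class WardflowError(Exception):
    """Base class for all package errors."""


class SchemaError(WardflowError):
    """An input table violates its declared schema (missing column, bad
    value, malformed timestamp).  Carries the offending rows when known."""

    def __init__(self, message, rows=None):
        super().__init__(message)
        self.rows = list(rows) if rows is not None else []


class ConfigError(WardflowError):
    """A configuration object violates one of its invariants.  The message
    names the offending field."""
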