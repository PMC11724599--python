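"""Exception hierarchy shared across the package."""


class TelemetryError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(TelemetryError):
    """A required column is missing or the schema mapping is wrong."""


class ParseError(TelemetryError):
    """Too many rows in an input file failed to parse."""


class ValidationError(TelemetryError):
    """Input values violate a data-model invariant."""
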