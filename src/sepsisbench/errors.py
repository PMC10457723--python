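"""Exception types shared across the package."""


class SepsisBenchError(Exception):
    """Base class for package errors."""


class ConfigurationError(SepsisBenchError):
    """A configuration value is invalid; the message names the field."""


class SchemaError(SepsisBenchError):
    """An input table does not conform to the expected CSV schema."""


class DomainError(SepsisBenchError):
    """An operation was asked for an argument outside its domain."""
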