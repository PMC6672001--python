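"""Exception hierarchy shared across the package."""


class CallosalError(Exception):
    """Base class for all package errors."""


class ValidationError(CallosalError, ValueError):
    """An input violates a documented precondition."""


class FormatError(CallosalError, ValueError):
    """An on-disk file cannot be parsed; the message names the offending field."""


class SchemaError(CallosalError, ValueError):
    """A table is missing required columns or has incompatible types."""


class PairingError(CallosalError, ValueError):
    """A homotopic (left/right) label cannot be paired."""
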