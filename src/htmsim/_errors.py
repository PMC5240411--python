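"""Exception types shared across the package."""


class HtmSimError(Exception):
    """Base class for all package errors."""


class ConfigError(HtmSimError):
    """A configuration value is invalid; the message names the field."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"invalid configuration field '{field}': {message}")


class ValidationError(HtmSimError):
    """Input data violates a precondition of an operation."""
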