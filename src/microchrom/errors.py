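"""Exception hierarchy shared across the pipeline stages."""


class MicrochromError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MicrochromError):
    """Invalid or missing configuration (thresholds, parameters)."""


class InputFormatError(MicrochromError):
    """A file does not conform to its declared format."""


class ChainParseError(InputFormatError):
    """Malformed UCSC chain file; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class UndefinedValueError(MicrochromError):
    """A statistic is undefined on the given input (empty denominator)."""
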