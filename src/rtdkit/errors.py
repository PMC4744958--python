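"""Exception hierarchy for rtdkit."""


class RtdkitError(Exception):
    """Base class for all rtdkit errors."""


class ParseError(RtdkitError):
    """A file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class ValidationError(RtdkitError):
    """A domain-model invariant was violated."""


class ConflictError(RtdkitError):
    """Two sources make irreconcilable claims about the same identifier."""


class CoordinateError(RtdkitError):
    """A feature lies outside the sequence it references."""


class FormatError(RtdkitError):
    """A tabular input does not have the expected columns."""


class InsufficientDataError(RtdkitError):
    """Too few observations for the requested statistic."""


class EmptyEventError(RtdkitError):
    """No transcript overlaps an event region."""
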