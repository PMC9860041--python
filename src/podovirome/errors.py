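"""Exception hierarchy shared by all pipeline stages."""


class PodoviromeError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(PodoviromeError):
    """A file could not be parsed; carries the offending line number when known."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class DuplicateIdError(ParseError):
    """An identifier occurred more than once where uniqueness is required."""


class ParameterError(PodoviromeError):
    """A parameter lies outside its documented domain."""


class DegenerateDataError(PodoviromeError):
    """Input data is degenerate for the requested statistic (e.g. zero variance)."""
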