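"""Exception hierarchy shared across the package."""


class PvSignalError(Exception):
    """Base class for all package-specific errors."""


class ParseError(PvSignalError):
    """A plain-text input table could not be parsed.

    Carries the offending line number where available.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ValidationError(PvSignalError):
    """A domain invariant was violated by otherwise well-formed input."""


class TermLookupError(PvSignalError, KeyError):
    """A term or class label did not resolve in the relevant dictionary."""

    def __str__(self) -> str:  # KeyError quotes its argument; keep the message readable
        return Exception.__str__(self)
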