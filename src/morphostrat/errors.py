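"""Exception hierarchy shared across the package."""


class MorphostratError(Exception):
    """Base class for all package errors."""


class ParseError(MorphostratError):
    """Malformed input file; carries the 1-based line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ValidationError(MorphostratError):
    """Structurally valid input that violates a domain invariant."""
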