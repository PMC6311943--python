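"""Exception hierarchy shared across the package."""


class CancerLncError(Exception):
    """Base class for all package errors."""


class ValidationError(CancerLncError, ValueError):
    """Invalid input data or parameters."""


class ParseError(ValidationError):
    """A file could not be parsed in the declared dialect.

    Carries the 1-based line number when available.
    """

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class DependencyError(CancerLncError):
    """A pipeline stage is missing an upstream artifact."""


class ConstantInputError(ValidationError):
    """A correlation was requested on a constant vector; the caller should
    treat the pair as having no defined correlation (no edge)."""
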