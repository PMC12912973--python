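"""Exception types shared across the toolkit."""


class RodletError(Exception):
    """Base class for all toolkit errors."""


class ValidationError(RodletError, ValueError):
    """Raised when inputs violate a documented precondition or invariant."""


class FormatError(RodletError, ValueError):
    """Raised when an on-disk file does not conform to the expected format."""


class UndefinedRateError(RodletError):
    """Raised when a rate is requested for a record containing no growth phase.

    Distinct from a zero rate: the quantity is undefined, not null.
    """


class FitFailureError(RodletError):
    """Raised when a nonlinear fit fails to converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class DegenerateTestError(RodletError):
    """Raised when a statistical test is degenerate (e.g. zero variance)."""
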