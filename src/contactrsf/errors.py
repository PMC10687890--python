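"""Exception hierarchy shared across the pipeline."""


class ContactRSFError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(ContactRSFError, ValueError):
    """An argument violates a documented precondition."""


class InsufficientDataError(ContactRSFError):
    """Not enough observations to perform the requested operation."""


class FitFailureError(ContactRSFError):
    """A model fit failed to converge; carries best-so-far diagnostics."""

    def __init__(self, message: str, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics


class DegenerateInputError(ContactRSFError):
    """Input is formally valid but degenerate (e.g. zero-area polygon)."""


class MissingDataError(ContactRSFError, KeyError):
    """A required layer or date is absent from the covariate stack."""
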