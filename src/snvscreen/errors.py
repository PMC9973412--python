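"""Exception types shared across the package."""


class SnvScreenError(Exception):
    """Base class for all package errors."""


class ValidationError(SnvScreenError, ValueError):
    """Invalid input data: malformed sequences, tables, or parameters."""


class FitError(SnvScreenError, RuntimeError):
    """A model fit failed to converge; carries diagnostics.

    Attributes
    ----------
    diagnostics : dict
        Per-start optimizer status collected before giving up.
    """

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}
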