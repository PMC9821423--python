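"""Exception hierarchy shared across the package."""


class TcrepError(Exception):
    """Base class for all package errors."""


class FormatError(TcrepError):
    """An input file does not conform to the expected tabular schema."""


class ValidationError(TcrepError):
    """Input values violate a documented precondition."""


class EmptyRepertoireError(ValidationError):
    """A repertoire has no productive clonotypes."""


class ConvergenceError(TcrepError):
    """An iterative fit failed to converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}
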