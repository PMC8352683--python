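"""Exception hierarchy shared across the package."""


class SymdxError(Exception):
    """Base class for all package-specific errors."""


class CodeRangeError(SymdxError, ValueError):
    """A level index (b, j, or t) falls outside its declared range."""


class UnknownCodeError(SymdxError, KeyError):
    """A disease code is not registered in the taxonomy."""


class RecordParseError(SymdxError, ValueError):
    """A records file is malformed; carries the offending row number."""

    def __init__(self, message: str, row: int | None = None):
        if row is not None:
            message = f"row {row}: {message}"
        super().__init__(message)
        self.row = row


class FitError(SymdxError, ValueError):
    """A classifier cannot be fitted (e.g. single-class input)."""


class SolverError(SymdxError, RuntimeError):
    """The SVM dual solver failed to converge; carries the pass count."""

    def __init__(self, message: str, n_iter: int | None = None):
        super().__init__(message)
        self.n_iter = n_iter


class TrainingError(SymdxError, RuntimeError):
    """Neural-network training produced NaN/overflow; carries the epoch."""

    def __init__(self, message: str, epoch: int | None = None):
        super().__init__(message)
        self.epoch = epoch


class ConfigError(SymdxError, ValueError):
    """A generator or cascade configuration is infeasible."""
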