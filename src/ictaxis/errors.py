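"""Exception hierarchy shared across the pipeline stages."""


class IctAxisError(Exception):
    """Base class for all package errors."""


class ValidationError(IctAxisError, ValueError):
    """Invalid input data or configuration (exit code 1 in the CLI)."""


class UndefinedResultError(IctAxisError, ArithmeticError):
    """A statistic is mathematically undefined for this input (e.g. zero variance)."""


class NumericalError(IctAxisError, ArithmeticError):
    """A numerical procedure failed (e.g. singular covariance matrix)."""
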