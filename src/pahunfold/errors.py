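"""Typed exceptions shared across the package."""


class PahunfoldError(Exception):
    """Base class for all package errors."""


class InvalidInputError(PahunfoldError, ValueError):
    """Raised when an argument violates a documented precondition."""


class CurveLoadError(PahunfoldError, ValueError):
    """Raised when a data file fails validation; carries row context."""


class ProcessingOrderError(PahunfoldError, RuntimeError):
    """Raised when pipeline stages are applied out of order (e.g. molar
    normalization before baseline subtraction, or twice)."""


class FitNotConvergedError(PahunfoldError, RuntimeError):
    """Raised when a result flagged ``converged=False`` is used where a
    converged fit is required."""
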