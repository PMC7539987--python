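"""Exception hierarchy shared across the analysis modules.

Exit-code mapping used by the command-line interface:
``UsageError`` -> 1, ``DataError`` -> 2, ``ConvergenceError`` -> 3.
"""


class XCQuenchError(Exception):
    """Base class for all package errors."""


class UsageError(XCQuenchError):
    """Invalid configuration, flags, or call arguments."""


class DataError(XCQuenchError):
    """Input data violate a precondition (domain, shape, sign, ...)."""


class DomainError(DataError):
    """A numeric argument lies outside its physically meaningful range."""


class UndefinedDIError(DataError):
    """De-epoxidation index requested with an empty xanthophyll pool."""


class AmbiguityError(DataError):
    """More than one chromatographic peak falls in a calibration window."""


class ConvergenceError(XCQuenchError):
    """A nonlinear fit failed to converge; carries last-iterate diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}
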