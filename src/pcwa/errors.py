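"""Exception hierarchy for the pcwa package."""


class PCWAError(Exception):
    """Base class for all pcwa errors."""


class InvalidParameterError(PCWAError, ValueError):
    """A parameter violates its contract (non-positive scale, bad range, ...)."""


class CalibrationError(PCWAError, RuntimeError):
    """Wavelet zero-mean / unit-norm calibration failed.

    Carries the residual of the failed solve in ``residual``.
    """

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class ResolutionError(PCWAError, ValueError):
    """A scale cannot be resolved at the trace's sampling interval."""


class FormatError(PCWAError, ValueError):
    """An input file does not satisfy the trace/event format contract."""
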