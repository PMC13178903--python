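"""Exception hierarchy shared across phantomflow.

The command-line layer maps these onto exit codes: parameter errors -> 2,
data errors -> 3, numerical failures -> 4.
"""


class PhantomflowError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(PhantomflowError, ValueError):
    """An argument or configuration value is invalid (exit code 2)."""


class DataError(PhantomflowError, ValueError):
    """An input file or in-memory dataset violates its contract (exit code 3)."""


class NumericalError(PhantomflowError, RuntimeError):
    """A solver or estimator failed numerically (exit code 4)."""


class IntegrationError(NumericalError):
    """Time integration produced a non-finite state."""

    def __init__(self, message: str, t_fail: float | None = None):
        super().__init__(message)
        self.t_fail = t_fail


class UnsupportedOracleError(ParameterError):
    """The requested analytic field kind has no closed-form pressure."""


class StagnationError(NumericalError):
    """Streamline tracing was seeded at (numerically) zero velocity."""


class SegmentationError(DataError):
    """No pulse triggers could be located in a pressure trace."""


class ProtocolError(ParameterError):
    """The discard/average pulse protocol cannot be applied (too few pulses)."""


class AlignmentError(DataError):
    """Two traces do not share a compatible time base."""


class FitError(NumericalError):
    """A parameter fit is rank-deficient or otherwise unsolvable."""
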