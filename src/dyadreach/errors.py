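"""Exception hierarchy shared across the package."""


class DyadReachError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(DyadReachError, ValueError):
    """A parameter violates its documented constraints; names the offending field."""


class ConvergenceError(DyadReachError, RuntimeError):
    """An iterative solver failed to converge within its iteration budget."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class SimulationDivergenceError(DyadReachError, RuntimeError):
    """A closed-loop simulation produced unbounded state."""


class SettlingError(DyadReachError, RuntimeError):
    """A pre-movement settling run ended with non-negligible velocity."""


class NoMovementError(DyadReachError, ValueError):
    """Velocity never exceeded the onset threshold in a recording."""


class TruncationError(DyadReachError, ValueError):
    """A recording is too short to cover the analysis window past onset."""


class ShapeError(DyadReachError, ValueError):
    """An array does not have the length/shape the operation requires."""


class DegenerateDataError(DyadReachError, ValueError):
    """Data degenerate for the requested statistic (e.g. an all-zero variance curve)."""


class CountError(DyadReachError, ValueError):
    """Wrong number of trials for an operation with a fixed-count contract."""


class SearchFailureError(DyadReachError, RuntimeError):
    """Every candidate in a search step failed to simulate."""


class DataFileError(DyadReachError, ValueError):
    """A data file is missing, malformed, or inconsistent; reports the location."""
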