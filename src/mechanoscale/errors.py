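"""Exception hierarchy for mechanoscale."""


class MechanoscaleError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(MechanoscaleError, ValueError):
    """A model or solver parameter violates its contract."""


class OutOfDomainError(InvalidParameterError):
    """A coordinate lies outside the domain of a profile or closed form."""


class SingularPointError(InvalidParameterError):
    """The radial ODE was evaluated at its coordinate singularity r = 0."""


class InsufficientResolutionError(InvalidParameterError):
    """A grid is too coarse for the requested quadrature."""


class InsufficientRangeError(InvalidParameterError):
    """A size sweep does not span a wide enough range for an exponent fit."""


class InvalidConfigurationError(InvalidParameterError):
    """A discrete dipole configuration is geometrically inadmissible."""


class SolverError(MechanoscaleError, RuntimeError):
    """Base class for numerical-solver failures."""


class NoSolutionError(SolverError):
    """The shooting bracket search found no admissible boundary value."""


class NonConvergenceError(SolverError):
    """An iteration exhausted its budget without meeting its tolerance.

    Carries the iteration trace so callers can diagnose oscillation and
    retry with smaller damping.
    """

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = list(trace) if trace is not None else []


class OracleFailureError(SolverError):
    """The independent collocation oracle failed to converge."""
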