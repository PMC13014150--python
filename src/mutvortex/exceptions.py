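"""Exception hierarchy.

Numerical failures are never silent: quadrature non-convergence, missing
roots, and simulator pathologies (extinction, burn-in failure) all raise.
"""


class MutvortexError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(MutvortexError, ValueError):
    """A model or configuration parameter violates its domain."""


class NumericalError(MutvortexError, ArithmeticError):
    """A quadrature or root-finding routine failed to converge."""


class NoRootError(NumericalError):
    """No sign change found for a root on the admissible interval.

    Carries the endpoint function values when available so callers can
    report why the root is missing (e.g. vnet < 0 everywhere when Ub = 0).
    """

    def __init__(self, msg, endpoints=None):
        super().__init__(msg)
        self.endpoints = endpoints


class BracketFailureError(NumericalError):
    """Outward bracket expansion hit its population-size cap."""


class PopulationExtinctError(MutvortexError):
    """Every individual in the simulated population has fitness zero."""


class BurnInFailureError(MutvortexError):
    """The burn-in criterion was never met within the run length."""


class InsufficientPointsError(MutvortexError):
    """Too few (N, vnet) points survive the inclusion filter for a line fit."""


class NoSolutionError(MutvortexError):
    """A matching problem (e.g. flux-matched Ne) has no solution in range."""
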