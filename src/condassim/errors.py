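"""Exception types shared across the package."""


class CondassimError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(CondassimError, ValueError):
    """A parameter value violates a structural invariant (e.g. dV = 0)."""


class OutOfRangeError(CondassimError, ValueError):
    """An input lies outside a certified/declared range."""


class IntegrationError(CondassimError, RuntimeError):
    """The forward ODE integrator failed to produce a valid trajectory."""


class SolverError(CondassimError, RuntimeError):
    """The NLP solver failed in a way that leaves no usable record."""
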