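"""Exception hierarchy for transglyc."""


class TransglycError(Exception):
    """Base class for all transglyc-specific errors."""


class DomainError(TransglycError, ValueError):
    """An input lies outside the physically meaningful domain."""


class ConvergenceError(TransglycError, RuntimeError):
    """A root-finding or optimization routine failed to reach tolerance.

    Carries the last residuals seen so callers can diagnose the failure.
    """

    def __init__(self, message: str, residuals=None):
        super().__init__(message)
        self.residuals = residuals


class IdentifiabilityError(TransglycError, ValueError):
    """The measurement design cannot jointly determine the requested constants."""


class InfeasibleTargetError(TransglycError, ValueError):
    """A design target is unreachable under the given constraints.

    ``asymptotic_yield`` reports the best yield achievable in the limit the
    search explored (e.g., very large sugar-donor excess).
    """

    def __init__(self, message: str, asymptotic_yield: float | None = None):
        super().__init__(message)
        self.asymptotic_yield = asymptotic_yield


class ParseError(TransglycError, ValueError):
    """A file could not be parsed into the expected structure."""
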