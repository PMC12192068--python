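"""Exception hierarchy for siirr."""


class SiirrError(Exception):
    """Base class for all siirr errors."""


class InvalidParameterError(SiirrError, ValueError):
    """A model parameter violates its admissibility constraints."""


class InvalidStateError(SiirrError, ValueError):
    """A compartment state is non-finite or inadmissible."""


class IntegrationError(SiirrError, RuntimeError):
    """The ODE integrator failed; carries the failure time."""

    def __init__(self, message: str, t_fail: float | None = None):
        super().__init__(message)
        self.t_fail = t_fail


class TrajectoryError(SiirrError, ValueError):
    """A trajectory violates its invariants or is malformed on disk."""


class AnalyticRegimeError(SiirrError, ValueError):
    """The closed-form solution family does not exist for these parameters."""


class AnalyticPoleError(SiirrError, ArithmeticError):
    """The general Riccati branch has a pole at the requested time."""

    def __init__(self, message: str, t_pole: float | None = None):
        super().__init__(message)
        self.t_pole = t_pole


class ConfigError(SiirrError, ValueError):
    """A run configuration is malformed or references an unknown scenario."""
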