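"""Exception hierarchy for seirkit."""


class SeirkitError(Exception):
    """Base class for all seirkit errors."""


class DomainError(SeirkitError, ValueError):
    """An argument is outside the mathematical domain of an operation."""


class ModelSpecError(SeirkitError, ValueError):
    """A flow specification is malformed (undeclared symbol, bad endpoint, ...)."""


class IntegrationError(SeirkitError, RuntimeError):
    """Adaptive integration could not proceed (step underflow, step budget, NaN)."""

    def __init__(self, message: str, t_reached: float | None = None):
        super().__init__(message)
        self.t_reached = t_reached


class ConfigError(SeirkitError, ValueError):
    """A run configuration is invalid; the message names the offending key."""
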