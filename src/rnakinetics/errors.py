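"""Exception hierarchy shared across the package."""


class RnaKineticsError(Exception):
    """Base class for all errors raised by rnakinetics."""


class ConfigurationError(RnaKineticsError):
    """A model/class/file configuration is malformed (bad form tag, unknown key, ...)."""


class DomainError(RnaKineticsError):
    """An input value is outside the mathematical domain of an operation."""


class NumericalError(RnaKineticsError):
    """A numerical routine (ODE integration) failed to converge."""

    def __init__(self, message: str, last_time: float | None = None):
        super().__init__(message)
        self.last_time = last_time


class FitError(RnaKineticsError):
    """Parameter estimation failed or was requested on unsuitable data."""
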