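"""Exception hierarchy shared across the package."""


class DenitkinError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(DenitkinError, ValueError):
    """A kinetic or state quantity violates its physical range."""


class ConfigurationError(DenitkinError, ValueError):
    """An internally inconsistent configuration (e.g. recycle without a sink pool)."""


class DegenerateInputError(DenitkinError, ValueError):
    """Input data that makes a derived quantity undefined (zero deltas, zero denominators)."""


class TableFormatError(DenitkinError, ValueError):
    """A delimited-text table does not match its declared schema."""


class IntegrationError(DenitkinError, RuntimeError):
    """The ODE integrator failed; carries the last time it reached."""

    def __init__(self, message: str, t_last: float | None = None):
        super().__init__(message)
        self.t_last = t_last


class FitError(DenitkinError, RuntimeError):
    """All optimizer starts failed."""
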