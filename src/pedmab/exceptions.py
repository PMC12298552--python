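"""Exception hierarchy shared across the package."""


class PedmabError(Exception):
    """Base class for all package errors."""


class RangeError(PedmabError, ValueError):
    """A numeric input lies outside the supported range."""

    def __init__(self, field: str, value, message: str = ""):
        self.field = field
        self.value = value
        super().__init__(f"{field}={value!r} out of range" + (f": {message}" if message else ""))


class UnsupportedAgeError(RangeError):
    """Requested age has no bundled physiology (e.g. neonates)."""


class ConfigError(PedmabError, ValueError):
    """A configuration, schema, or consistency problem."""


class DomainError(PedmabError, ValueError):
    """A mathematical-domain violation (non-positive dose, zero rate, ...)."""


class DesignError(PedmabError, ValueError):
    """A study design is internally inconsistent."""


class SolverError(PedmabError, RuntimeError):
    """The ODE integrator failed; carries the last accepted time."""

    def __init__(self, message: str, last_time: float | None = None):
        self.last_time = last_time
        super().__init__(message if last_time is None else f"{message} (last accepted t={last_time:.6g} d)")
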