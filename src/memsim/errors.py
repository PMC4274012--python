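"""Exception hierarchy shared across the package."""


class MemsimError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(MemsimError, ValueError):
    """A kinetic or configuration parameter is outside its domain."""


class InvalidStateError(MemsimError, ValueError):
    """A cell state violates an invariant (e.g. negative counts)."""


class SimulationError(MemsimError, RuntimeError):
    """The stochastic simulation cannot proceed (bad horizon, overflow)."""


class ConfigError(MemsimError, ValueError):
    """A run configuration file is malformed or contains unknown keys."""


class SelectionError(MemsimError, LookupError):
    """A founder class is empty in the supplied population snapshot."""


class InsufficientDataError(MemsimError, ValueError):
    """A statistic was requested on fewer observations than it needs."""


class UndefinedStatisticError(MemsimError, ArithmeticError):
    """The statistic is undefined for this input (zero mean, zero variance,
    constant series)."""
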