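"""Exception hierarchy for the hibrain package."""


class HibrainError(Exception):
    """Base class for all package errors."""


class ConfigError(HibrainError):
    """Invalid configuration or parameter file content."""


class DomainError(HibrainError, ValueError):
    """An argument lies outside its physically meaningful domain."""


class ConvergenceError(HibrainError, RuntimeError):
    """A solver (steady state, ODE integration, optimiser) failed to converge."""


class ParseError(HibrainError, ValueError):
    """A delimited input file violates the documented schema."""
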