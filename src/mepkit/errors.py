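"""Exception hierarchy shared across modules."""


class MepkitError(Exception):
    """Base class for all package errors."""


class InputError(MepkitError, ValueError):
    """Malformed or inconsistent user-supplied data."""


class ConfigError(MepkitError, ValueError):
    """Invalid configuration value."""


class NumericalStabilityError(MepkitError, RuntimeError):
    """A numerical procedure diverged (e.g. integrator blow-up)."""


class ConvergenceError(MepkitError, RuntimeError):
    """An iterative solver failed to reach its tolerance."""
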