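"""Exception types shared across the package."""


class EmspopError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(EmspopError, ValueError):
    """A configuration value is missing, non-finite or out of range."""


class InputError(EmspopError, ValueError):
    """Malformed or out-of-contract input data."""


class UndefinedStatisticError(EmspopError, ValueError):
    """A statistic was requested on an empty (or otherwise degenerate) set."""


class EstimationError(EmspopError, RuntimeError):
    """An estimator could not produce a value (degenerate spectrum etc.)."""
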