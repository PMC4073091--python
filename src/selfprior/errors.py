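"""Exception taxonomy used across the package."""


class SelfPriorError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(SelfPriorError, ValueError):
    """Invalid task, cohort or run configuration."""


class InputError(SelfPriorError, ValueError):
    """Malformed or insufficient input data (missing columns, too few trials)."""


class FitError(SelfPriorError, RuntimeError):
    """Maximum-likelihood fit failed or the data are degenerate for fitting."""


class EstimationError(SelfPriorError, RuntimeError):
    """A regression or derived estimate could not be computed."""


class StatisticError(SelfPriorError, RuntimeError):
    """A group-level statistic is undefined for the given inputs."""


class ParseError(SelfPriorError, ValueError):
    """A file did not conform to the documented dialect/schema."""
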