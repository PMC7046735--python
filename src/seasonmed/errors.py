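"""Exception hierarchy shared across the package."""


class SeasonmedError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(SeasonmedError, ValueError):
    """A configuration object violates one of its invariants."""


class CohortValidationError(SeasonmedError, ValueError):
    """A cohort table violates the schema (bad column, range, or parse)."""


class FitError(SeasonmedError, RuntimeError):
    """A regression model could not be fitted (rank deficiency, divergence)."""


class DegenerateDataError(SeasonmedError, ValueError):
    """Input data carry no usable variation for the requested operation."""


class BootstrapError(SeasonmedError, RuntimeError):
    """Too many bootstrap resamples failed to produce an estimate."""
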