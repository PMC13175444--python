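"""Exception hierarchy for the pxmode package."""


class PxmodeError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(PxmodeError):
    """Invalid generator or analysis configuration."""


class ValidationError(PxmodeError):
    """Input data violates a declared contract (range, completeness, coding)."""


class EstimationError(PxmodeError):
    """A model fit or contrast cannot be computed (separation, rank deficiency,
    empty cells, degenerate variances)."""


class TruthUnavailableError(PxmodeError):
    """Simulation ground truth was requested from a dataset that has none."""
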