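"""Exception hierarchy shared across the package."""


class SfCouplingError(Exception):
    """Base class for all package-specific errors."""


class InvalidSpecError(SfCouplingError, ValueError):
    """A cohort / run specification violates its invariants."""


class InvalidInputError(SfCouplingError, ValueError):
    """An input matrix, vector, or table violates a precondition."""


class DegenerateInputError(SfCouplingError, ValueError):
    """An input is structurally valid but numerically degenerate
    (zero variance, isolated node, too few usable edges)."""


class GenerationError(SfCouplingError, RuntimeError):
    """The synthetic generator failed to produce a valid object
    within its retry budget."""


class ConfigError(SfCouplingError, ValueError):
    """Model configuration is internally inconsistent."""


class TrainingError(SfCouplingError, RuntimeError):
    """Optimization diverged (non-finite loss)."""
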