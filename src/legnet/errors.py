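"""Exception hierarchy shared across the package."""


class LegnetError(Exception):
    """Base class for all package-specific errors."""


class SizingError(LegnetError, ValueError):
    """A grid, territory, or cohort is too small for the requested operation."""


class ConfigurationError(LegnetError, ValueError):
    """A configuration value is inconsistent or out of its allowed range."""


class ContractError(LegnetError, ValueError):
    """An input violates a documented shape or value contract."""


class AtlasIntegrityError(LegnetError, ValueError):
    """An atlas violates one of its structural invariants."""


class DegenerateSignalError(LegnetError, ValueError):
    """A time series is numerically degenerate (e.g. zero variance) where a
    well-defined correlation is required."""


class FormatError(LegnetError, ValueError):
    """A file on disk does not parse as the expected format."""


class TrainingError(LegnetError, RuntimeError):
    """Optimization diverged; carries the loss history for diagnosis."""

    def __init__(self, message, history=None):
        super().__init__(message)
        self.history = history
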