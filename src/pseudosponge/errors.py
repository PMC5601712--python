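"""Exception hierarchy shared across the pipeline."""


class PseudospongeError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(PseudospongeError, ValueError):
    """A simulation or pipeline configuration value is invalid."""


class PlacementError(PseudospongeError):
    """The toy genome is too small to place the requested genes."""


class DomainError(PseudospongeError, ValueError):
    """An argument is outside the mathematical domain of an operation."""


class ScaleError(PseudospongeError):
    """An expression matrix is on the wrong scale for the operation."""


class FitError(PseudospongeError):
    """A statistical model could not be fitted (non-identifiable input)."""
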