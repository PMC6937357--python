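"""Exception hierarchy shared across the package."""


class PetIQError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(PetIQError):
    """A configuration value is missing, unknown, or inconsistent."""


class PlacementError(PetIQError):
    """A geometric object falls outside its allowed container."""


class UndefinedRatioError(PetIQError):
    """A ratio was requested with a zero or negative denominator."""


class ShapeError(PetIQError):
    """Array shapes or grids do not match."""


class ReconDivergenceError(PetIQError):
    """The penalized objective decreased persistently during optimization."""

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = trace


class FitError(PetIQError):
    """A model fit was degenerate or failed to converge."""
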