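"""Exception hierarchy shared across the package."""


class CycloPureError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(CycloPureError):
    """Invalid simulation or run configuration."""


class UndefinedSurvivalYieldError(CycloPureError):
    """Survival yield is undefined (total ion current is zero)."""


class DegenerateFitError(CycloPureError):
    """The data do not determine the model (flat curve, rank deficiency...)."""


class FitConvergenceError(CycloPureError):
    """Iterative fit hit its iteration cap; carries the best-so-far parameters."""

    def __init__(self, message, params=None, rss=None):
        super().__init__(message)
        self.params = params
        self.rss = rss


class GridMismatchError(CycloPureError):
    """Voltage or wavenumber grids do not line up as required."""


class ExtrapolationError(CycloPureError):
    """Requested point lies outside the span of the data."""


class PredictionError(CycloPureError):
    """Model inversion failed (no admissible root, ambiguity, zero slope)."""


class FormatError(CycloPureError):
    """Malformed input file; carries a line number where applicable."""

    def __init__(self, message, line=None, path=None):
        if line is not None:
            message = f"{message} (line {line})"
        if path is not None:
            message = f"{path}: {message}"
        super().__init__(message)
        self.line = line
        self.path = path


class PrecursorWindowWarning(UserWarning):
    """No peak found inside the precursor isolation window; SY reported as 0."""
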