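"""Exception hierarchy shared across the package."""


class CliffscoutError(Exception):
    """Base class for all package-specific errors."""


class GridFormatError(CliffscoutError, ValueError):
    """Malformed raster file (bad header key, row length mismatch, ...)."""


class ExtentError(CliffscoutError, ValueError):
    """A point or index falls outside the grid extent."""


class InvalidInputError(CliffscoutError, ValueError):
    """Input violates an operation's preconditions."""


class UndefinedRatioError(CliffscoutError, ZeroDivisionError):
    """A ratio with an empty denominator (empty region, empty matrix...)."""


class InfeasibleSamplingError(CliffscoutError, ValueError):
    """A stratum does not contain enough candidate cells to sample from."""


class DegenerateSampleError(CliffscoutError, ValueError):
    """A statistical test received a degenerate sample (e.g. zero variance)."""
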