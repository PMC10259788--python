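"""Exception types raised across the package."""


class CircoutlierError(Exception):
    """Base class for package-specific errors."""


class UndefinedDirectionError(CircoutlierError, ValueError):
    """The mean direction is undefined (zero resultant vector)."""


class InvalidParameterError(CircoutlierError, ValueError):
    """A distribution or procedure parameter is outside its valid range."""


class InvalidQuantileError(CircoutlierError, KeyError):
    """A requested quantile level is not present in a cut-off table."""


class DegenerateFitError(CircoutlierError, RuntimeError):
    """A regression fit could not be computed (degenerate design or weights)."""
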