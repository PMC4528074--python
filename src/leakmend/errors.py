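"""Exception hierarchy shared across the package."""


class LeakmendError(Exception):
    """Base class for all package-specific errors."""


class ShapeError(LeakmendError, ValueError):
    """Input array dimensions are incompatible with the operation."""


class ParameterError(LeakmendError, ValueError):
    """A scalar parameter is outside its valid range."""


class DegenerateInputError(LeakmendError, ValueError):
    """Input data are rank-deficient or otherwise geometrically degenerate."""


class SolverError(LeakmendError, RuntimeError):
    """An iterative solver failed to converge within its iteration cap."""
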