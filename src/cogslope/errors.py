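"""Exception hierarchy used across the package."""


class CogslopeError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(CogslopeError, ValueError):
    """An argument is outside its documented domain."""


class SpecError(CogslopeError, ValueError):
    """A generative or model specification violates its invariants."""


class AlignmentError(CogslopeError, ValueError):
    """Two inputs that must be keyed/ordered identically are not."""


class StructuralError(CogslopeError, ValueError):
    """The data lack a column/structure the operation requires."""


class IdentificationError(CogslopeError, ValueError):
    """The requested model is not identified."""


class ConsistencyError(CogslopeError, ValueError):
    """Cross-references between results and inputs do not resolve."""


class ConvergenceError(CogslopeError, RuntimeError):
    """An iterative fit failed to converge."""
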