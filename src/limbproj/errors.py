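"""Exception hierarchy for limbproj."""


class LimbprojError(Exception):
    """Base class for all package errors."""


class GeometryError(LimbprojError):
    """Contract violation in a geometric primitive (e.g. non-unit axis)."""


class DegenerateGeometryError(GeometryError):
    """Input geometry is degenerate (zero vector, coincident points, ...)."""


class InsufficientDataError(GeometryError):
    """Too few / rank-deficient points for a fit."""


class ConvergenceError(LimbprojError):
    """Iterative solver failed to converge."""


class ConstructionError(LimbprojError):
    """Limb construction could not realize the requested targets."""


class ValidationError(LimbprojError):
    """Invalid user input (file schema, parameter ranges, pose grid)."""
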