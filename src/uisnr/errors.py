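"""Exception hierarchy for the uisnr package."""


class UisnrError(Exception):
    """Base class for all package-specific errors."""


class GeometryError(UisnrError, ValueError):
    """A geometric construction is impossible on the given grid."""


class DegenerateGeometryError(GeometryError):
    """Requested geometry collapses below the resolution of the grid."""


class PlacementError(GeometryError):
    """An organ/inclusion does not fit inside the enclosing body."""


class EmptyBodyError(GeometryError):
    """Operation requires at least one non-air voxel."""


class EmptyShellError(DegenerateGeometryError):
    """No air voxel satisfies the shell distance predicate."""


class DielectricLookupError(UisnrError, KeyError):
    """Tissue/frequency pair not resolvable from the dielectric table."""


class SolverError(UisnrError, RuntimeError):
    """Iterative field solve failed to reach the requested residual.

    Carries the relative-residual history so callers can diagnose
    stagnation vs. slow convergence.
    """

    def __init__(self, message, residual_history=None):
        super().__init__(message)
        self.residual_history = list(residual_history or [])


class ConfigError(UisnrError, ValueError):
    """Run configuration is inconsistent or incomplete."""
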