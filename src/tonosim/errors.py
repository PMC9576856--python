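"""Exception hierarchy for tonosim."""


class TonosimError(Exception):
    """Base class for all package errors."""


class InvalidDeformationError(TonosimError):
    """Deformation gradient with non-positive determinant."""


class NumericRangeError(TonosimError):
    """Overflow of the exponential fibre term at extreme stretch."""


class GeometryError(TonosimError):
    """Geometrically infeasible configuration (e.g. thickness >= radius)."""


class WatertightError(TonosimError):
    """Cavity surface is not closed; carries the offending boundary edges."""

    def __init__(self, message, boundary_edges=None):
        super().__init__(message)
        self.boundary_edges = list(boundary_edges or [])


class OrientationError(TonosimError):
    """Inconsistently oriented surface facets."""


class FitFailureError(TonosimError):
    """Material parameter fit failed (degenerate data)."""


class ConvergenceError(TonosimError):
    """Nonlinear solve or staggered coupling failed to converge."""


class NoApplanationError(TonosimError):
    """No applanation event found in a deformation history (weak jet)."""


class NoConcavityError(TonosimError):
    """Profile has fewer than two bending peaks; peak distance undefined."""


class ConfigError(TonosimError):
    """Invalid run configuration."""
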