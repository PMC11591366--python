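"""Exception hierarchy shared across the pipeline.

All validation failures derive from :class:`ValidationError` so callers (and
the CLI's exit-code mapping) can distinguish bad inputs, degenerate geometry,
and numerical failures.
"""


class ChondrometryError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(ChondrometryError, ValueError):
    """Inputs violate a documented precondition (bad shapes, counts, ranges)."""


class DegenerateGeometryError(ValidationError):
    """Geometry does not constrain the fit (coplanar sphere points, collinear
    plane points, collinear registration targets, near-parallel frame axes)."""


class AmbiguousMatchError(ChondrometryError):
    """Two marker correspondences explain the data equally well (symmetric
    marker layout); the caller must supply labels."""


class ConvergenceError(ChondrometryError):
    """An iterative fit failed to converge; carries diagnostics in args."""


class EmptySubregionError(ValidationError):
    """A subregion-selection stage removed every vertex; names the stage."""


class InsufficientCoverageError(ValidationError):
    """Too few valid points survive filtering to report statistics."""


class FrameQualityError(ChondrometryError):
    """Anatomical-frame landmark fits are too poor to trust (large residuals)."""
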