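"""Exception hierarchy for cquant.

Every module raises subclasses of :class:`CQuantError` so callers (and the
CLI) can catch one base type. Names mirror the failure modes of the
operations that raise them.
"""


class CQuantError(Exception):
    """Base class for all cquant errors."""


class FormatError(CQuantError):
    """A file could not be parsed as the expected format, or violates an
    invariant of the format (e.g. a non-invertible NIfTI affine, dangling
    mesh indices)."""


class UnsupportedCellError(FormatError):
    """A surface file contains non-triangle cells."""


class EmptyResultError(CQuantError):
    """An operation produced an empty result (seed outside the intensity
    range, label absent from a segmentation, empty corridor...)."""


class ResolutionError(CQuantError):
    """A phantom or measurement was requested at a resolution too coarse to
    represent the geometry."""


class PreconditionError(CQuantError):
    """A geometric precondition was violated (vein too fat for the chamber,
    too few landmarks, degenerate axis...)."""


class OutOfSupportError(CQuantError):
    """Points fall outside the valid support of a B-spline lattice."""

    def __init__(self, message: str, indices=None):
        super().__init__(message)
        self.indices = indices


class DomainError(CQuantError):
    """Two images share no world-space overlap, or data are unusable
    (all-NaN similarity)."""


class SingularElementError(CQuantError):
    """A degenerate (zero-area) element prevented a per-element solve."""

    def __init__(self, message: str, triangle_index: int | None = None):
        super().__init__(message)
        self.triangle_index = triangle_index


class BoundaryError(CQuantError):
    """Dirichlet boundary sets are empty, overlapping, or touching."""


class TopologyError(CQuantError):
    """A vertex loop is not a closed edge loop, or a mesh lacks the
    required topology."""


class LocationError(CQuantError):
    """A seed/target point lies outside the segmented region."""


class ConnectivityError(CQuantError):
    """No path exists between two points in a voxel graph."""


class NoOpeningError(CQuantError):
    """The cross-sectional area profile never rises: no chamber opening."""


class NoIntersectionError(CQuantError):
    """A clip plane does not intersect the object."""


class NormalisationError(CQuantError):
    """Non-positive normalisation constant."""


class CorrespondenceError(CQuantError):
    """Two per-element arrays do not share a length / element basis."""


class DivergenceWarning(UserWarning):
    """A streamline exceeded its path-length cap."""


class CollinearRingWarning(UserWarning):
    """A landmark ring is collinear: its area is zero."""


class ClampedSampleWarning(UserWarning):
    """Image samples outside the volume were clamped to the border."""
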