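"""Exception hierarchy for the contour-QA pipeline."""


class SegQAError(Exception):
    """Base class for all segqa errors."""


class GeometryError(SegQAError):
    """Invalid geometric input (extent, alignment, grid mismatch)."""


class ExtentError(GeometryError):
    """A polygon falls outside the voxel grid's in-plane extent."""


class SliceAlignmentError(GeometryError):
    """A contour slice z does not map to any grid plane within tolerance."""


class GridMismatchError(GeometryError):
    """Two masks that must share a voxel grid do not."""


class DegenerateStructureError(GeometryError):
    """An operation would leave a structure with no slices."""


class UndefinedMetricError(SegQAError):
    """The requested similarity metric is undefined for these inputs."""


class InsufficientDataError(SegQAError):
    """Too few observations to estimate reference statistics."""


class DomainError(SegQAError):
    """A value lies outside its permitted domain (e.g. DSC outside [0, 1])."""


class RoutingError(SegQAError):
    """A record was routed to limits/summaries for the wrong organ."""


class StructureLookupError(SegQAError):
    """A named ROI/structure is absent from a file."""


class FrameConsistencyError(SegQAError):
    """Gold and auto structures sit in different patient frames of reference."""


class IncompleteReviewError(SegQAError):
    """A flagged failure has no review annotation."""


class AnnotationConflictError(SegQAError):
    """More than one annotation targets the same (patient, organ) record."""


class ConsistencyError(SegQAError):
    """Aggregate bookkeeping is inconsistent (e.g. n_evaluated < n_flagged)."""


class ConfigurationError(SegQAError):
    """Pipeline configuration is incomplete or contradictory."""
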