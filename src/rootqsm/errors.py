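"""Exception hierarchy for rootqsm.

All package-specific failures derive from :class:`RootQsmError` so callers
can catch one base class; subclasses mirror the pipeline stages.
"""


class RootQsmError(Exception):
    """Base class for all rootqsm errors."""


class CloudIOError(RootQsmError):
    """Unreadable/unwritable point-cloud file or malformed record."""


class EmptyCloudError(RootQsmError):
    """A point cloud with zero points where at least one is required."""


class GeometryError(RootQsmError):
    """Degenerate geometric input (parallel axes, zero vectors, ...)."""


class ParameterError(RootQsmError):
    """Invalid parameter value (non-positive patch diameter, bad grid, ...)."""


class EstimationError(RootQsmError):
    """Density/spacing estimation failed (all patches degenerate)."""


class SegmentationError(RootQsmError):
    """Stump/base/segment detection failed."""


class FitError(RootQsmError):
    """Cylinder least-squares fit failed (degenerate or diverged)."""


class StructureError(RootQsmError):
    """Invalid tree structure (cycle, broken parent link)."""


class ReferenceFormatError(RootQsmError):
    """Malformed digitized-reference (MTG-dialect) file."""


class InputError(RootQsmError):
    """Mismatched or invalid analysis inputs."""
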