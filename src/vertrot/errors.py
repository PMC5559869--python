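"""Exception hierarchy for vertrot."""


class VertrotError(Exception):
    """Base class for all vertrot errors."""


class ParameterError(VertrotError, ValueError):
    """An operation was called with invalid parameters."""


class GeometryError(VertrotError):
    """Degenerate or invalid geometry (self-intersecting polygon, collinear points)."""


class ReferenceUndefinedError(VertrotError):
    """The anteroposterior reference cannot be projected into the endplate plane."""


class EmptyInputError(VertrotError, ValueError):
    """An operation received an empty mask, list or table."""


class InsufficientDataError(VertrotError, ValueError):
    """Fewer data points than the statistic requires."""


class ResolutionError(VertrotError):
    """Voxel or pixel spacing too coarse to resolve the requested shape."""


class EmptySliceError(VertrotError):
    """The requested reformat plane does not intersect the volume."""


class DataError(VertrotError):
    """Inconsistent tabular input, e.g. duplicate (patient, level) records."""
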