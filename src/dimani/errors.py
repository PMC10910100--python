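"""Exception hierarchy shared across the package.

All are ValueError subclasses so callers that only care about "bad input"
can catch one base type; the CLI maps any of these to exit code 1 with a
one-line diagnostic.
"""


class DimaniError(ValueError):
    """Base class for all validation failures raised by this package."""


class ValidationError(DimaniError):
    """An input violates a documented invariant (non-unit bvec, non-SPD tensor, ...)."""


class ConsistencyError(DimaniError):
    """Two inputs that must describe the same acquisition disagree
    (e.g. gradient-table length vs number of 4D volumes)."""


class GeometryError(DimaniError):
    """Two volumes that must share a voxel grid (shape and affine) do not.

    Raised instead of silently resampling: resampling label maps would
    corrupt overlap statistics, so inputs must be co-registered upstream.
    """
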