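"""Exception hierarchy.

Every error raised by the library derives from :class:`VoxelKitError` so
callers (and the CLI) can distinguish library failures from programming
errors. Validation errors carry enough context to name the offending axis
or field.
"""


class VoxelKitError(Exception):
    """Base class for all voxelkit errors."""


class BoundsError(VoxelKitError):
    """A requested range extends beyond the volume extents."""

    def __init__(self, axis: str, message: str):
        self.axis = axis
        super().__init__(message)


class EmptyRangeError(VoxelKitError):
    """A half-open interval with start >= stop."""

    def __init__(self, axis: str, message: str):
        self.axis = axis
        super().__init__(message)


class ResolutionError(VoxelKitError):
    """Resolution level outside [0, num_resolutions)."""


class DtypeError(VoxelKitError):
    """Data dtype does not match the resource dtype (no silent casts)."""


class ShapeError(VoxelKitError):
    """Array shape does not match the request box."""


class CapabilityError(VoxelKitError):
    """The remote does not declare a capability required for the operation."""


class NotFoundError(VoxelKitError):
    """Resource (or HTTP endpoint) does not exist."""


class AlreadyExistsError(VoxelKitError):
    """Resource creation attempted at an occupied URI."""


class IncompletePlanError(VoxelKitError):
    """stitch() was handed fewer blocks than the plan requires."""


class UpstreamUnavailableError(VoxelKitError):
    """A relay could not reach its upstream and the request is not cached."""


class ConfigError(VoxelKitError):
    """Malformed or unresolvable application configuration."""


class TransferError(VoxelKitError):
    """A transfer job failed a precondition."""
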