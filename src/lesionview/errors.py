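"""Exception hierarchy shared across the package."""


class LesionViewError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(LesionViewError):
    """An input violates a documented precondition or invariant."""


class VolumeFormatError(LesionViewError):
    """A volume file exists but is not usable (wrong rank, bad values)."""


class NoForegroundError(LesionViewError):
    """A crop kernel was requested for a volume with no voxel above threshold."""


class GenerationError(LesionViewError):
    """A synthetic phantom could not satisfy its lesion-placement request."""


class ShapeError(LesionViewError):
    """Array extents do not match an operation's contract."""


class TransferError(LesionViewError):
    """Pretrained weights could not be copied into a model."""
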