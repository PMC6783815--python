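"""Exception hierarchy."""


class MorphoctError(Exception):
    """Base class for package errors."""


class VolumeFormatError(MorphoctError, ValueError):
    """Raised for unreadable or malformed volume files."""


class TableFormatError(MorphoctError, ValueError):
    """Raised for malformed descriptor tables."""


class DegenerateGeometryError(MorphoctError, ValueError):
    """Raised when a geometric primitive is degenerate (coplanar points,
    open mesh, empty mask, ...)."""


class ExtractionError(MorphoctError, RuntimeError):
    """Raised when the plant-extraction pipeline fails; the message is
    prefixed with the failing stage name."""


class PhantomError(MorphoctError, ValueError):
    """Raised for invalid phantom specifications."""
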