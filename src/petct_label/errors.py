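"""Exception hierarchy shared across the pipeline."""


class PetCtError(Exception):
    """Base class for all package errors."""


class ValidationError(PetCtError, ValueError):
    """An input violates a documented precondition or invariant."""


class UnsupportedFormatError(PetCtError, ValueError):
    """A raster file is not single-frame 8-bit grayscale."""


class DegenerateGeometryError(PetCtError, ValueError):
    """Control points or a transform are too degenerate to use
    (collinear landmarks, singular linear part, empty foreground)."""


class BoundsError(PetCtError, IndexError):
    """A coordinate or index falls outside the image or list it refers to."""


class PairingError(PetCtError, LookupError):
    """A PET/CT series index has no partner image."""


class ImageIOError(PetCtError, OSError):
    """A raster or annotation file could not be read or written."""
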