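"""Exception hierarchy for fanlm.

All library errors derive from :class:`FanlmError` so callers (and the CLI)
can distinguish user-facing problems from genuine bugs.
"""


class FanlmError(Exception):
    """Base class for all fanlm errors."""


class InvalidParameterError(FanlmError, ValueError):
    """A parameter value violates its contract (negative sigma, even window, ...)."""


class InvalidInputError(FanlmError, ValueError):
    """An input image or array violates its contract (shape mismatch, too small, ...)."""


class ImageFormatError(FanlmError, ValueError):
    """A file could not be read or written in a supported image format."""


class MetadataError(FanlmError, ValueError):
    """Image metadata (affine/header) is inconsistent with the data being written."""
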