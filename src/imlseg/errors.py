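"""Exception hierarchy for the segmentation pipeline.

Each CLI exit code maps onto one branch of this tree: input problems
(unreadable files, bad formats), co-registration violations, and label
drawings that cannot support training.
"""


class ImlsegError(Exception):
    """Base class for all package errors."""


class InputError(ImlsegError):
    """Unreadable, malformed, or contract-violating input."""


class UnsupportedFormatError(InputError):
    """Readable file but a pixel type or layout we do not handle."""


class CoRegistrationError(ImlsegError):
    """Input images do not share a voxel grid within tolerance."""


class InsufficientLabelsError(ImlsegError):
    """Fewer than two distinct nonzero classes in a label drawing."""


class MissingClassError(ImlsegError):
    """A class present in the drawing has no voxels on the working grid."""

    def __init__(self, class_id: int, message: str | None = None):
        self.class_id = class_id
        super().__init__(message or f"class {class_id} has no labeled voxels")


class EmptySeedsError(ImlsegError):
    """A geodesic map was requested with an empty seed mask."""
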