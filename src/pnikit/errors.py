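"""Exception hierarchy used across the package."""


class PnikitError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(PnikitError, ValueError):
    """A value violates a documented precondition or invariant."""


class SizingError(ValidationError):
    """A geometric request does not fit: patch larger than image, canvas too
    small for the requested structures, map too small for a pyramid depth."""


class ShapeError(ValidationError):
    """Arrays that must share dimensions do not."""


class FormatError(PnikitError):
    """A file could not be parsed as the expected on-disk format."""


class PlacementError(SizingError):
    """Rejection sampling exhausted its retry budget while placing
    non-overlapping structures on the synthetic canvas."""


class TrainingError(PnikitError):
    """Training failed (empty dataset, NaN loss).  Carries the step index at
    which the failure occurred when applicable."""

    def __init__(self, message: str, step: int | None = None):
        super().__init__(message)
        self.step = step
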