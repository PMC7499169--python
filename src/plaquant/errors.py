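"""Exception and warning hierarchy.

Each error class maps to a distinct CLI exit code (see :mod:`plaquant.cli`)
so that batch callers can distinguish configuration mistakes from
per-image processing failures.
"""


class PlaquantError(Exception):
    """Base class for all errors raised by plaquant."""

    exit_code = 1


class ConfigurationError(PlaquantError):
    """The experiment configuration is inconsistent (e.g. a patient has
    selected moments but no reference moment)."""

    exit_code = 2


class ValidationError(PlaquantError):
    """A domain invariant is violated (e.g. two reference moments for the
    same patient)."""

    exit_code = 2


class UnreadableImageError(PlaquantError):
    """An image file is missing or cannot be decoded."""

    exit_code = 3


class EmptyDentalAreaError(PlaquantError):
    """Segmentation produced no surviving dental component."""

    exit_code = 4


class DegenerateSegmentationError(PlaquantError):
    """A dental mask needed for a computation is empty."""

    exit_code = 4


class ParameterError(PlaquantError):
    """Processing parameters are out of their valid range (e.g. l > delta)."""

    exit_code = 2


class DegenerateImageWarning(UserWarning):
    """The image has no intensity spread; thresholding yields an empty
    foreground."""
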