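"""Exception hierarchy shared across the package."""


class PetBpnnError(Exception):
    """Base class for all package-specific errors."""


class FormatError(PetBpnnError):
    """A file could not be read or is not in a supported format."""


class ValidationError(PetBpnnError, ValueError):
    """Input data violates a documented contract (bad label, duplicate id, ...)."""


class ShapeError(PetBpnnError, ValueError):
    """Array dimensions are inconsistent with what the operation requires."""


class DegenerateInputError(PetBpnnError, ValueError):
    """The input is empty of usable signal (e.g. an all-background image)."""


class UndefinedMetricError(PetBpnnError, ZeroDivisionError):
    """A classification metric has a zero denominator."""
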