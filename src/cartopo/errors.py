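"""Typed exceptions.

Undefined quantities raise rather than return sentinel numbers; batch-level
code is expected to catch, log and skip.
"""


class CartopoError(Exception):
    """Base class for all package errors."""


class ValidationError(CartopoError, ValueError):
    """Invalid input data or specification."""


class NyquistError(ValidationError):
    """Requested wavelength below twice the sampling step."""


class UndefinedWavelengthError(CartopoError):
    """No inter-maxima spacings available on an axis (or in a sector)."""

    def __init__(self, axis: str, sector: str | None = None):
        self.axis = axis
        self.sector = sector
        where = f"sector {sector}, axis {axis}" if sector else f"axis {axis}"
        super().__init__(f"wavelength undefined: no gradient maxima spacings ({where})")


class DegenerateDataError(CartopoError):
    """Rank statistics undefined (e.g. all observations identical)."""


class EmptySegmentationError(CartopoError):
    """Cartilage segmentation produced an empty mask."""


class PackingError(CartopoError):
    """Requested synthetic cell count cannot be placed without overlap."""
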