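"""Exception hierarchy for sicklestain.

All package-specific failures derive from :class:`SickleStainError` so callers
can catch everything with one clause; the leaf classes distinguish the failure
modes that the analysis pipeline treats differently (bad inputs vs. degenerate
results vs. refused renderings).
"""


class SickleStainError(Exception):
    """Base class for all sicklestain errors."""


class DomainError(SickleStainError, ValueError):
    """An argument is outside the domain a function is defined on."""


class FormatError(SickleStainError, TypeError):
    """An image or table does not have the required structure (e.g. no Blue channel)."""


class SaturationError(SickleStainError):
    """Requested stain amplitudes would clip >1% of stain pixels at 255.

    Saturation breaks the linearity between pixel intensity and deposited
    hemoglobin mass that both indices rely on, so the generator refuses to
    render such a stain rather than silently producing a biased image.
    """


class LayoutError(SickleStainError):
    """A sheet layout cannot hold the requested stains without overlap."""


class NoStainError(SickleStainError):
    """A radial profile is indistinguishable from background."""


class UndefinedIndexError(SickleStainError, ArithmeticError):
    """An index ratio is undefined (zero ring mean), as opposed to an invalid input."""


class FittingError(SickleStainError):
    """A threshold or calibration fit is impossible on the given data."""


class MergedStainWarning(UserWarning):
    """A connected component spans more than 1.5x the maximum stain diameter."""
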