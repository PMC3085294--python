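"""Exception hierarchy for the ebtbr pipeline.

Every error raised on a data-dependent path derives from :class:`EbtbrError`
so batch drivers can isolate per-image failures without masking genuine bugs
(``TypeError`` etc. still propagate).
"""


class EbtbrError(Exception):
    """Base class for all pipeline errors."""


class UnsupportedImageError(EbtbrError):
    """Raster file exists but is not a 3-channel 8/16-bit RGB image."""


class DegenerateImageError(EbtbrError):
    """Constant image: full-range rescaling (and every ratio downstream) is undefined."""


class EmptyMaskError(EbtbrError):
    """Segmentation selected zero foreground pixels."""


class OpenContourError(EbtbrError):
    """Edge band does not enclose a region, so contour filling is impossible."""


class ShapeMismatchError(EbtbrError):
    """Channel and mask (or other paired arrays) are not congruent."""


class PlacementError(EbtbrError):
    """A measurement square cannot be placed inside the cutout."""


class DegenerateDataError(EbtbrError):
    """Data admit no answer: zero median, all-tied sample, empty square, ..."""


class ParameterError(EbtbrError, ValueError):
    """A configuration or phantom parameter violates its stated range."""


class ConfigError(EbtbrError):
    """Run configuration file is unreadable or inconsistent."""


class BatchError(EbtbrError):
    """Every row of a batch failed."""
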