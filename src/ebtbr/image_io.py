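"""Raster I/O, blue-channel extraction and full-range intensity rescaling.

Brain-slice photographs enter the pipeline as RGB rasters (PNG/TIFF/JPEG,
8 or 16 bits per channel). Because RGB is an additive colour model, the blue
channel tracks the amount of Evans blue dye in the tissue, so all downstream
analysis runs on the blue plane alone. Intensities are kept on the uint16
scale throughout: 8-bit inputs are promoted by x257 (so 255 maps exactly to
65535) and each image is stretched so its observed minimum sits at 0 and its
maximum at 65535 before segmentation and median measurement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

from .exceptions import DegenerateImageError, ParameterError, UnsupportedImageError

log = logging.getLogger(__name__)

UINT16_MAX = 65535
#: promotion factor taking 8-bit intensities onto the uint16 scale (255*257 == 65535)
PROMOTE_8_TO_16 = 257

_TIFF_SUFFIXES = {".tif", ".tiff"}
_JPEG_SUFFIXES = {".jpg", ".jpeg"}


@dataclass
class SliceImage:
    """One coronal brain-slice photograph: rows x cols x 3 (RGB order).

    ``pixels`` may be any integer or float dtype; values must lie in
    ``[0, 2**bit_depth)``. Float arrays are accepted so that exact affine
    transforms of an image (for invariance checks) stay exact.
    """

    pixels: np.ndarray
    bit_depth: int
    source_path: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            nchan = px.shape[2] if px.ndim == 3 else 1
            raise UnsupportedImageError(
                f"expected a rows x cols x 3 RGB array, got {nchan} channel(s) "
                f"with shape {px.shape}"
            )
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise UnsupportedImageError("image must have at least one row and column")
        if self.bit_depth not in (8, 16):
            raise ParameterError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if px.size and (px.min() < 0 or px.max() >= 2**self.bit_depth):
            raise ParameterError(
                f"intensities outside [0, 2^{self.bit_depth}): "
                f"min={px.min()}, max={px.max()}"
            )
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class ChannelImage:
    """A single (blue) intensity plane on the uint16 scale, values in [0, 65535]."""

    pixels: np.ndarray
    rescaled: bool = False

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ParameterError(f"channel image must be 2-D, got shape {px.shape}")
        if px.size == 0:
            raise ParameterError("channel image is empty")
        if px.min() < 0 or px.max() > UINT16_MAX:
            raise ParameterError(
                f"channel intensities outside [0, {UINT16_MAX}]: "
                f"min={px.min()}, max={px.max()}"
            )
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def load_image(path: str | Path) -> SliceImage:
    """Read a PNG/TIFF/JPEG raster as an RGB :class:`SliceImage`.

    Channel order is RGB regardless of the on-disk layout (decoders already
    normalise this); ``bit_depth`` reflects the file's sample depth.
    Grayscale or CMYK files are rejected with the offending channel count.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    suffix = path.suffix.lower()
    if suffix in _TIFF_SUFFIXES:
        arr = tifffile.imread(str(path))
    else:
        if suffix in _JPEG_SUFFIXES:
            log.warning(
                "%s: JPEG is lossy; compression artefacts perturb square medians", path
            )
        with Image.open(path) as im:
            if im.mode == "CMYK":
                raise UnsupportedImageError(f"{path}: CMYK (4-channel) input unsupported")
            arr = np.asarray(im)
    if arr.ndim == 2:
        raise UnsupportedImageError(f"{path}: grayscale (1-channel) input unsupported")
    if arr.ndim != 3 or arr.shape[2] != 3:
        nchan = arr.shape[2] if arr.ndim == 3 else 1
        raise UnsupportedImageError(f"{path}: expected 3 channels, got {nchan}")
    bit_depth = 16 if arr.dtype.itemsize > 1 else 8
    return SliceImage(pixels=arr, bit_depth=bit_depth, source_path=str(path))


def save_image(img: SliceImage | np.ndarray, path: str | Path) -> Path:
    """Write an RGB raster. TIFF carries 8- or 16-bit samples; PNG is 8-bit.

    16-bit data routed to PNG raises: the installed PNG encoder only handles
    8 bits per channel for RGB, so fixtures and phantoms use TIFF.
    """
    path = Path(path)
    arr = img.pixels if isinstance(img, SliceImage) else np.asarray(img)
    depth = img.bit_depth if isinstance(img, SliceImage) else (16 if arr.dtype.itemsize > 1 else 8)
    arr = np.rint(arr).astype(np.uint16 if depth == 16 else np.uint8)
    suffix = path.suffix.lower()
    if suffix in _TIFF_SUFFIXES:
        tifffile.imwrite(str(path), arr)
    elif suffix == ".png":
        if depth == 16:
            raise UnsupportedImageError(
                "16-bit RGB PNG is not supported by the encoder; write TIFF instead"
            )
        Image.fromarray(arr).save(path)
    else:
        raise UnsupportedImageError(f"unsupported output format: {path.suffix}")
    return path


def save_mask_png(mask: np.ndarray, path: str | Path) -> Path:
    """Write a binary mask as an 8-bit PNG (foreground 255) for audit."""
    path = Path(path)
    arr = (np.asarray(mask) > 0).astype(np.uint8) * 255
    Image.fromarray(arr).save(path)
    return path


def extract_blue_channel(img: SliceImage) -> ChannelImage:
    """Select the blue (third) plane; promote 8-bit values onto the uint16 scale."""
    blue = img.pixels[:, :, 2]
    if img.bit_depth == 8:
        blue = blue.astype(np.float64) * PROMOTE_8_TO_16
        if np.issubdtype(img.pixels.dtype, np.integer):
            blue = blue.astype(np.uint16)
    return ChannelImage(pixels=blue, rescaled=False)


def rescale_full_range(ch: ChannelImage) -> ChannelImage:
    """Stretch intensities linearly so min -> 0 and max -> 65535 (uint16 maximum).

    Rounded to the nearest integer. Idempotent, and invariant under positive
    affine transforms of the input. A constant image has no dynamic range and
    raises :class:`DegenerateImageError` (every downstream ratio would be
    undefined).
    """
    px = np.asarray(ch.pixels, dtype=np.float64)
    mn = px.min()
    mx = px.max()
    if mx == mn:
        raise DegenerateImageError(
            f"constant image (all pixels {mn!r}): full-range rescaling undefined"
        )
    out = np.rint((px - mn) * float(UINT16_MAX) / (mx - mn)).astype(np.uint16)
    return ChannelImage(pixels=out, rescaled=True)
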