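"""Cutout cropping, ROI definition and placement of the four measurement squares.

After segmentation the image is cropped to the outermost brain pixel (the
mask's tight bounding box). The upper 20% of the cutout approximates the
cortex between the surface and the ventricles and is the region of interest.
Four side x side squares (default 50 px) are placed in cutout coordinates:

* ``target`` — centred on the user-picked seed (the cranial-window centre),
  inside the ROI of the ipsilateral hemisphere;
* ``background`` — its horizontal mirror about the cutout's vertical midline,
  in the contralateral hemisphere;
* ``norm_ipsi`` / ``norm_contra`` — same two columns, in a bottom band clearly
  outside the ROI; their medians normalise each side.

Conventions: 0-based (row, col) with row 0 at the top; square extents are
half-open intervals ``[corner, corner + side)``. The target's position is also
stored as distances from the mask bounding-box edges so a placement can be
reproduced on a re-segmented image.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .exceptions import EmptyMaskError, ParameterError, PlacementError
from .image_io import ChannelImage, SliceImage, UINT16_MAX
from .segmentation import BrainMask

log = logging.getLogger(__name__)

DEFAULT_ROI_FRACTION = 0.20
DEFAULT_SIDE = 50
DEFAULT_MARGIN = 5


@dataclass
class CutoutImage:
    """Channel + mask cropped to the mask's tight bounding box.

    ``offset`` is the (row, col) of the cutout origin in the full image.
    """

    pixels: np.ndarray
    mask: np.ndarray
    offset: tuple[int, int]

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        self.mask = np.asarray(self.mask)
        if self.pixels.shape != self.mask.shape:
            raise ParameterError(
                f"cutout pixels {self.pixels.shape} and mask {self.mask.shape} differ"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class RoiBand:
    """Upper band of the cutout: rows ``[0, stop)`` with ``stop = ceil(fraction * rows)``."""

    row_range: tuple[int, int]
    fraction: float

    @property
    def stop(self) -> int:
        return self.row_range[1]


@dataclass
class SquarePlacement:
    """Top-left corners (cutout coordinates) of the four measurement squares."""

    side: int
    target: tuple[int, int]
    background: tuple[int, int]
    norm_ipsi: tuple[int, int]
    norm_contra: tuple[int, int]
    #: (top, bottom, left, right) distances from the target square to the
    #: mask bounding-box edges — the stored, reproducible seed representation.
    seed_distances: tuple[int, int, int, int]

    def corners(self) -> dict[str, tuple[int, int]]:
        return {
            "target": self.target,
            "background": self.background,
            "norm_ipsi": self.norm_ipsi,
            "norm_contra": self.norm_contra,
        }


def crop_to_mask(ch: ChannelImage, mask: BrainMask) -> CutoutImage:
    """Tight bounding-box crop of channel and mask down to the outermost brain pixel."""
    fg = np.asarray(mask.pixels) > 0
    if not fg.any():
        raise EmptyMaskError("cannot crop: mask has no foreground pixels")
    rows = np.flatnonzero(fg.any(axis=1))
    cols = np.flatnonzero(fg.any(axis=0))
    r0, r1 = int(rows[0]), int(rows[-1]) + 1
    c0, c1 = int(cols[0]), int(cols[-1]) + 1
    return CutoutImage(
        pixels=np.asarray(ch.pixels)[r0:r1, c0:c1],
        mask=fg[r0:r1, c0:c1].astype(np.uint8),
        offset=(r0, c0),
    )


def define_roi(cut: CutoutImage, fraction: float = DEFAULT_ROI_FRACTION) -> RoiBand:
    """Upper ``fraction`` of the cutout (default 20%), rounded up to whole rows."""
    if not 0 < fraction <= 1:
        raise ParameterError(f"roi fraction must be in (0, 1], got {fraction}")
    stop = math.ceil(fraction * cut.shape[0])
    return RoiBand(row_range=(0, stop), fraction=fraction)


def _clamp(v: int, lo: int, hi: int) -> int:
    return max(lo, min(hi, v))


def _build_placement(
    cut: CutoutImage, row_t: int, col_t: int, roi: RoiBand, side: int, margin: int
) -> SquarePlacement:
    rows, cols = cut.shape
    col_bg = cols - col_t - side
    if row_t >= roi.stop:
        raise PlacementError(
            f"target square rows [{row_t}, {row_t + side}) do not intersect the "
            f"ROI rows [0, {roi.stop})"
        )
    r_norm = rows - side - margin
    if r_norm < 0:
        raise PlacementError(
            f"norm squares do not fit: cutout has {rows} rows, need side {side} + margin {margin}"
        )
    if r_norm < roi.stop:
        raise PlacementError(
            f"norm squares (rows [{r_norm}, {r_norm + side})) fall inside the ROI "
            f"rows [0, {roi.stop}); they must sit clearly outside it"
        )
    if col_bg == col_t:
        log.warning("seed on the vertical midline: target and background coincide in columns")
    fg = cut.mask > 0
    for name, (r, c) in {
        "target": (row_t, col_t),
        "background": (row_t, col_bg),
        "norm_ipsi": (r_norm, col_t),
        "norm_contra": (r_norm, col_bg),
    }.items():
        frac = fg[r : r + side, c : c + side].mean()
        log.info("square %s corner=(%d,%d) foreground fraction %.3f", name, r, c, frac)
    return SquarePlacement(
        side=side,
        target=(row_t, col_t),
        background=(row_t, col_bg),
        norm_ipsi=(r_norm, col_t),
        norm_contra=(r_norm, col_bg),
        seed_distances=(row_t, rows - row_t - side, col_t, cols - col_t - side),
    )


def place_squares(
    cut: CutoutImage,
    seed: tuple[int, int],
    roi: RoiBand,
    side: int = DEFAULT_SIDE,
    margin: int = DEFAULT_MARGIN,
) -> SquarePlacement:
    """Place the four squares from a seed point (cutout coordinates).

    The target is the side x side square centred on the seed, shifted inward
    if the centred extent would leave the cutout. The background square is the
    horizontal mirror ``col_bg = cols - col_target - side`` on the same rows;
    the norm squares share the two columns and sit ``margin`` pixels above the
    cutout's bottom edge.
    """
    rows, cols = cut.shape
    r, c = int(seed[0]), int(seed[1])
    if not (0 <= r < rows and 0 <= c < cols):
        raise PlacementError(f"seed {seed} outside cutout of shape {cut.shape}")
    if side > rows or side > cols:
        raise PlacementError(f"side {side} exceeds cutout {cut.shape}")
    row_t = _clamp(r - side // 2, 0, rows - side)
    col_t = _clamp(c - side // 2, 0, cols - side)
    if (row_t, col_t) != (r - side // 2, c - side // 2):
        log.warning("seed %s near edge: target clamped to corner (%d, %d)", seed, row_t, col_t)
    return _build_placement(cut, row_t, col_t, roi, side, margin)


def place_from_distances(
    cut: CutoutImage,
    seed_distances: tuple[int, int, int, int],
    roi: RoiBand,
    side: int = DEFAULT_SIDE,
    margin: int = DEFAULT_MARGIN,
) -> SquarePlacement:
    """Re-place the squares from stored mask-edge distances (round-trip of a placement)."""
    top, bottom, left, right = (int(v) for v in seed_distances)
    rows, cols = cut.shape
    if top + bottom + side != rows or left + right + side != cols:
        log.warning(
            "stored distances %s inconsistent with cutout %s at side %d; using top/left",
            seed_distances, cut.shape, side,
        )
    if not (0 <= top <= rows - side and 0 <= left <= cols - side):
        raise PlacementError(
            f"stored distances {seed_distances} place the target outside cutout {cut.shape}"
        )
    return _build_placement(cut, top, left, roi, side, margin)


def mirror_seed(seed: tuple[int, int], cut: CutoutImage) -> tuple[int, int]:
    """Seed that reproduces a placement on the horizontally mirrored cutout.

    With half-open square extents and even ``side``, the column ``cols - col``
    maps the target onto the exact mirror of the original target (and the
    background onto the mirror of the original background).
    """
    return (seed[0], cut.shape[1] - seed[1])


def render_overlay(cut: CutoutImage, sq: SquarePlacement) -> SliceImage:
    """RGB copy of the cutout with the four squares outlined, as a visual control.

    Target outlined in blue, background and norm squares in white (one-pixel
    outlines; interior pixels untouched).
    """
    base = np.rint(np.asarray(cut.pixels, dtype=np.float64)).astype(np.uint16)
    rgb = np.stack([base, base, base], axis=2)
    blue = (0, 0, UINT16_MAX)
    white = (UINT16_MAX, UINT16_MAX, UINT16_MAX)
    for name, (r, c) in sq.corners().items():
        color = blue if name == "target" else white
        s = sq.side
        for k in range(3):
            rgb[r, c : c + s, k] = color[k]
            rgb[r + s - 1, c : c + s, k] = color[k]
            rgb[r : r + s, c, k] = color[k]
            rgb[r : r + s, c + s - 1, k] = color[k]
    return SliceImage(pixels=rgb, bit_depth=16, source_path="<overlay>")
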