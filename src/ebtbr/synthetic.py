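"""Synthetic brain-slice phantoms with known masks and leak ratios.

A phantom is an RGB raster emulating a photographed coronal slice: a bright
elliptical "brain" on a dark dish background, left-right symmetric about a
vertical midline (the two hemispheres), with an optional disc of elevated
blue intensity in the upper part of the right hemisphere standing in for
Evans blue extravasation under a cranial window. A global gain/offset mimics
illumination differences between photographs and additive Gaussian noise
mimics the sensor. The ground truth (ellipse mask, leak disc, constructed
leak ratio) makes every pipeline stage testable without animal data.

The leak is multiplicative on the blue channel, so the constructed
``leak_ratio`` is exactly the TBR an ideal pipeline should recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .exceptions import ParameterError
from .image_io import SliceImage, UINT16_MAX

#: group label, group size and constructed leak ratio of the four-arm study
#: design this generator emulates: a positive control with early barrier
#: disruption (DHC, n=8, clear leak), a sham arm (n=6), an endothelin-1 arm
#: (n=7) and a remote spreading-depolarization arm (n=5), the latter three
#: without early leak.
DEFAULT_COHORT_SPECS: tuple[tuple[str, int, float], ...] = (
    ("DHC", 8, 1.6),
    ("sham", 6, 1.0),
    ("ET1", 7, 1.0),
    ("SD", 5, 1.0),
)

#: attenuation of the red/green planes relative to blue (the dye is blue)
RED_ATTENUATION = 0.45
GREEN_ATTENUATION = 0.30


@dataclass
class PhantomParams:
    """Geometry, intensity and noise settings of one phantom.

    Defaults reproduce the acquisition this generator emulates: 1040 x 1392
    pixels, 16 bits per channel. ``brain_axes`` are the ellipse semi-axes
    (semi-height, semi-width); ``None`` picks 38% / 40% of the image size.
    ``leak_center``/``leak_radius`` default to a disc in the upper part of
    the right hemisphere, inside the upper-20% band of the brain's bounding
    box. ``noise_sd`` is the additive Gaussian sigma in uint16 intensity
    units (2% of dynamic range ~ 1311).
    """

    rows: int = 1040
    cols: int = 1392
    brain_axes: tuple[float, float] | None = None
    background_level: float = 0.0
    tissue_level: float = 30000.0
    leak_ratio: float = 1.0
    leak_center: tuple[float, float] | None = None
    leak_radius: float | None = None
    noise_sd: float = 0.0
    illumination_gain: float = 1.0
    illumination_offset: float = 0.0
    seed: int = 0

    def resolved(self) -> "PhantomParams":
        """Fill in the geometry defaults that depend on the image size."""
        p = replace(self)
        if p.brain_axes is None:
            p.brain_axes = (0.38 * p.rows, 0.40 * p.cols)
        if p.leak_radius is None:
            p.leak_radius = 0.08 * p.brain_axes[0]
        if p.leak_center is None:
            a, b = p.brain_axes
            # upper part of the right (ipsilateral) hemisphere, within the
            # upper 20% of the brain's bounding box
            p.leak_center = (p.rows / 2 - 0.7 * a, p.cols / 2 + 0.35 * b)
        return p

    def validate(self) -> "PhantomParams":
        p = self.resolved()
        if p.rows < 1 or p.cols < 1:
            raise ParameterError("phantom must have positive size")
        if p.tissue_level <= p.background_level:
            raise ParameterError(
                f"tissue_level ({p.tissue_level}) must exceed background_level "
                f"({p.background_level})"
            )
        if p.leak_ratio < 1:
            raise ParameterError(f"leak_ratio must be >= 1, got {p.leak_ratio}")
        if p.noise_sd < 0 or p.illumination_gain <= 0:
            raise ParameterError("noise_sd must be >= 0 and illumination_gain > 0")
        a, b = p.brain_axes
        cy, cx = p.rows / 2, p.cols / 2
        ly, lx = p.leak_center
        r = p.leak_radius
        if ly >= cy:
            raise ParameterError("leak disc must lie in the upper half of the brain")
        # the whole disc must fit inside the ellipse: check the four extreme points
        for dy, dx in ((r, 0), (-r, 0), (0, r), (0, -r)):
            if ((ly + dy - cy) / a) ** 2 + ((lx + dx - cx) / b) ** 2 > 1.0:
                raise ParameterError(
                    f"leak disc (center {p.leak_center}, radius {r:.1f}) leaves the "
                    f"brain ellipse (axes {a:.1f} x {b:.1f})"
                )
        return p


@dataclass
class PhantomTruth:
    """Ground truth of one phantom: brain mask, leak disc, constructed ratio."""

    mask: np.ndarray
    leak_region: np.ndarray
    true_ratio: float


def ellipse_mask(rows: int, cols: int, center: tuple[float, float],
                 axes: tuple[float, float]) -> np.ndarray:
    """Binary ellipse: pixels whose centers satisfy the ellipse inequality."""
    yy, xx = np.ogrid[:rows, :cols]
    cy, cx = center
    a, b = axes
    return (((yy - cy) / a) ** 2 + ((xx - cx) / b) ** 2 <= 1.0).astype(np.uint8)


def generate_phantom(params: PhantomParams) -> tuple[SliceImage, PhantomTruth]:
    """Render one phantom; identical seed gives a bit-identical image."""
    p = params.validate()
    rng = np.random.default_rng(p.seed)
    cy, cx = p.rows / 2, p.cols / 2
    brain = ellipse_mask(p.rows, p.cols, (cy, cx), p.brain_axes)
    yy, xx = np.ogrid[: p.rows, : p.cols]
    ly, lx = p.leak_center
    leak = ((yy - ly) ** 2 + (xx - lx) ** 2 <= p.leak_radius**2) & (brain > 0)

    blue = np.where(brain > 0, p.tissue_level, p.background_level).astype(np.float64)
    blue[leak] *= p.leak_ratio
    img = np.stack([RED_ATTENUATION * blue, GREEN_ATTENUATION * blue, blue], axis=2)
    img = p.illumination_gain * img + p.illumination_offset
    if p.noise_sd > 0:
        img = img + rng.normal(0.0, p.noise_sd, size=img.shape)
    img = np.rint(np.clip(img, 0, UINT16_MAX)).astype(np.uint16)
    truth = PhantomTruth(mask=brain, leak_region=leak.astype(np.uint8),
                         true_ratio=p.leak_ratio)
    return (
        SliceImage(pixels=img, bit_depth=16, source_path=f"<phantom seed={p.seed}>"),
        truth,
    )


def suggested_seed_point(params: PhantomParams) -> tuple[int, int]:
    """Cranial-window seed for this phantom, in full-image coordinates.

    The leak centre — also used for leak-free phantoms, where it marks the
    position the window would occupy.
    """
    p = params.resolved()
    return (int(round(p.leak_center[0])), int(round(p.leak_center[1])))


def suggested_margin(params: PhantomParams) -> int:
    """Bottom-band margin keeping the norm squares inside the elliptical brain.

    An ellipse is narrow near its bottom edge, so the default 5-px margin
    would push the norm squares into background; 15% of the brain's bounding
    box height keeps them in tissue at the norm columns.
    """
    p = params.resolved()
    return int(round(0.15 * 2 * p.brain_axes[0]))


def seed_from_truth(truth: PhantomTruth) -> tuple[int, int]:
    """Window seed (full-image coordinates) from a phantom's truth: the leak centroid.

    The leak disc is rendered into the truth even when its ratio is 1.0, so
    leak-free phantoms get the homologous window position.
    """
    rows, cols = np.nonzero(truth.leak_region)
    if rows.size == 0:
        raise ParameterError("truth has an empty leak region; no window position defined")
    return (int(round(rows.mean())), int(round(cols.mean())))


def margin_from_truth(truth: PhantomTruth) -> int:
    """Norm-square margin (15% of the brain bounding-box height) from the truth mask."""
    rows = np.flatnonzero(truth.mask.any(axis=1))
    return int(round(0.15 * (rows[-1] - rows[0] + 1)))


def generate_cohort(
    group_specs: Sequence[tuple[str, int, float]] = DEFAULT_COHORT_SPECS,
    shared: PhantomParams | None = None,
    seed: int = 0,
    jitter: float = 0.05,
) -> list[tuple[SliceImage, PhantomTruth, str]]:
    """Generate a multi-group cohort with per-animal jitter.

    Each animal perturbs the shared geometry and tissue level by a uniform
    factor in ``1 +/- jitter`` (``1 +/- 2*jitter`` for the tissue level) and
    draws fresh sensor noise; the constructed leak ratio is exactly the
    group's. Deterministic given ``seed``. ``jitter=0`` with a single animal
    reduces to :func:`generate_phantom`.
    """
    if not group_specs:
        raise ParameterError("group_specs must name at least one group")
    for label, n, ratio in group_specs:
        if n < 1:
            raise ParameterError(f"group {label!r} must have n >= 1, got {n}")
        if ratio < 1:
            raise ParameterError(f"group {label!r} leak_ratio must be >= 1, got {ratio}")
    base = (shared or PhantomParams()).resolved()
    rng = np.random.default_rng(seed)
    out: list[tuple[SliceImage, PhantomTruth, str]] = []
    for label, n, ratio in group_specs:
        for _ in range(n):
            a, b = base.brain_axes
            fy, fx = 1 + jitter * rng.uniform(-1, 1, size=2)
            tissue = base.tissue_level * (1 + 2 * jitter * rng.uniform(-1, 1))
            child_seed = int(rng.integers(0, 2**31))
            p = replace(
                base,
                brain_axes=(a * fy, b * fx),
                tissue_level=tissue,
                leak_ratio=ratio,
                leak_center=None,   # re-derive from the jittered axes
                leak_radius=None,
                seed=child_seed,
            )
            img, truth = generate_phantom(p)
            out.append((img, truth, label))
    return out
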