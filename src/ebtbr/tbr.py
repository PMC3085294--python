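"""Target-to-background ratio (TBR) — the pipeline's core statistic.

The median blue intensity of the cranial-window square (target) is divided by
that of the mirrored contralateral square (background), after normalising each
side by the median of a remote bottom square in the same hemisphere:

    rel_ipsi   = median(target)     / median(norm_ipsi)
    rel_contra = median(background) / median(norm_contra)
    TBR        = rel_ipsi / rel_contra

TBR > 1 indicates ipsilateral Evans blue excess, i.e. extravasation through a
disrupted blood-brain barrier in the windowed hemisphere. The method is
semiquantitative: only relative (group-level) comparisons are meaningful.

An optional single-normalizer variant divides both sides by the ipsilateral
bottom square, matching an alternative reading of the procedure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable

import numpy as np
import pandas as pd

from .exceptions import BatchError, DegenerateDataError, EbtbrError, PlacementError
from .image_io import ChannelImage, SliceImage, extract_blue_channel, load_image, rescale_full_range
from .roi_geometry import (
    DEFAULT_MARGIN,
    DEFAULT_ROI_FRACTION,
    DEFAULT_SIDE,
    CutoutImage,
    SquarePlacement,
    crop_to_mask,
    define_roi,
    place_squares,
)
from .segmentation import BrainMask, FilterConfig, segment_brain

log = logging.getLogger(__name__)


@dataclass
class TBRResult:
    """The four square medians, the two normalized side values and the ratio."""

    median_target: float
    median_background: float
    median_norm_ipsi: float
    median_norm_contra: float
    rel_ipsi: float
    rel_contra: float
    tbr: float
    animal_id: str = ""
    group_label: str = ""

    def to_dict(self) -> dict[str, Any]:
        return {
            "animal_id": self.animal_id,
            "group": self.group_label,
            "median_target": self.median_target,
            "median_background": self.median_background,
            "median_norm_ipsi": self.median_norm_ipsi,
            "median_norm_contra": self.median_norm_contra,
            "rel_ipsi": self.rel_ipsi,
            "rel_contra": self.rel_contra,
            "tbr": self.tbr,
        }


def square_median(
    cut: CutoutImage,
    corner: tuple[int, int],
    side: int,
    exclude_background: bool = False,
) -> float:
    """Median intensity of the side x side square at ``corner`` (top-left).

    Even pixel counts take the mean of the two central order statistics. With
    ``exclude_background`` pixels outside the brain mask are dropped first
    (their near-zero values would bias the median toward zero); the exclusion
    count is logged.
    """
    r, c = int(corner[0]), int(corner[1])
    rows, cols = cut.shape
    if not (0 <= r and 0 <= c and r + side <= rows and c + side <= cols):
        raise PlacementError(
            f"square corner {corner} side {side} outside cutout of shape {cut.shape}"
        )
    patch = np.asarray(cut.pixels[r : r + side, c : c + side], dtype=np.float64)
    if exclude_background:
        inside = np.asarray(cut.mask[r : r + side, c : c + side]) > 0
        n_excluded = patch.size - int(inside.sum())
        if n_excluded == patch.size:
            raise DegenerateDataError(
                f"square at {corner} contains no brain pixels (all {patch.size} masked out)"
            )
        if n_excluded:
            log.info("square at %s: excluded %d background pixel(s)", corner, n_excluded)
        patch = patch[inside]
    return float(np.median(patch))


def compute_tbr(
    cut: CutoutImage,
    sq: SquarePlacement,
    animal_id: str = "",
    group_label: str = "",
    single_normalizer: bool = False,
) -> TBRResult:
    """Populate a :class:`TBRResult` from a cutout and square placement.

    Medians exclude masked-out background pixels. Any zero median makes the
    ratio undefined and raises, naming the offending square.
    """
    med = {
        name: square_median(cut, corner, sq.side, exclude_background=True)
        for name, corner in sq.corners().items()
    }
    for name, m in med.items():
        if m <= 0:
            raise DegenerateDataError(
                f"median of {name} square is {m}; ratio undefined (division degeneracy)"
            )
    norm_contra = med["norm_ipsi"] if single_normalizer else med["norm_contra"]
    rel_ipsi = med["target"] / med["norm_ipsi"]
    rel_contra = med["background"] / norm_contra
    return TBRResult(
        median_target=med["target"],
        median_background=med["background"],
        median_norm_ipsi=med["norm_ipsi"],
        median_norm_contra=med["norm_contra"],
        rel_ipsi=rel_ipsi,
        rel_contra=rel_contra,
        tbr=rel_ipsi / rel_contra,
        animal_id=animal_id,
        group_label=group_label,
    )


@dataclass
class RunSpec:
    """One image's worth of batch input: where it is, who it is, how to process it."""

    image: SliceImage | str | Path
    seed_point: tuple[int, int]
    animal_id: str = ""
    group_label: str = ""
    filter_config: FilterConfig = field(default_factory=FilterConfig)
    seed_space: str = "image"  # "image" or "cutout" coordinates for seed_point


@dataclass
class AssessResult:
    """Full provenance of one image's assessment."""

    tbr: TBRResult
    placement: SquarePlacement
    mask: BrainMask
    cutout: CutoutImage


def assess_image(
    image: SliceImage | str | Path,
    seed_point: tuple[int, int],
    filter_config: FilterConfig | None = None,
    roi_fraction: float = DEFAULT_ROI_FRACTION,
    side: int = DEFAULT_SIDE,
    margin: int = DEFAULT_MARGIN,
    seed_space: str = "image",
    single_normalizer: bool = False,
    rescale: bool = True,
    animal_id: str = "",
    group_label: str = "",
) -> AssessResult:
    """Run the whole pipeline on one slice image.

    Blue channel -> full-range rescale -> segmentation -> cutout -> ROI ->
    square placement from the seed -> TBR. ``seed_space`` says whether the
    seed point is given in full-image or cutout coordinates.
    """
    img = load_image(image) if isinstance(image, (str, Path)) else image
    ch = extract_blue_channel(img)
    if rescale:
        ch = rescale_full_range(ch)
    cfg = filter_config or FilterConfig()
    mask = segment_brain(ch, cfg)
    cut = crop_to_mask(ch, mask)
    if seed_space == "image":
        seed = (seed_point[0] - cut.offset[0], seed_point[1] - cut.offset[1])
    elif seed_space == "cutout":
        seed = tuple(seed_point)
    else:
        raise PlacementError(f"seed_space must be 'image' or 'cutout', got {seed_space!r}")
    roi = define_roi(cut, roi_fraction)
    sq = place_squares(cut, seed, roi, side=side, margin=margin)
    result = compute_tbr(
        cut, sq, animal_id=animal_id, group_label=group_label,
        single_normalizer=single_normalizer,
    )
    return AssessResult(tbr=result, placement=sq, mask=mask, cutout=cut)


def batch_tbr(
    runs: Iterable[RunSpec],
    roi_fraction: float = DEFAULT_ROI_FRACTION,
    side: int = DEFAULT_SIDE,
    margin: int = DEFAULT_MARGIN,
    single_normalizer: bool = False,
) -> tuple[pd.DataFrame, list[AssessResult | None]]:
    """Assess a batch of images; failures are recorded per row, not raised.

    Returns the results table (input order preserved; an ``error`` column
    holds the failure message for rows that did not complete) and the list of
    per-row :class:`AssessResult` details (None for failed rows). A batch in
    which every row failed raises :class:`BatchError`.
    """
    rows: list[dict[str, Any]] = []
    details: list[AssessResult | None] = []
    n_ok = 0
    for spec in runs:
        try:
            res = assess_image(
                spec.image,
                spec.seed_point,
                filter_config=spec.filter_config,
                roi_fraction=roi_fraction,
                side=side,
                margin=margin,
                seed_space=spec.seed_space,
                single_normalizer=single_normalizer,
                animal_id=spec.animal_id,
                group_label=spec.group_label,
            )
        except (EbtbrError, FileNotFoundError) as err:
            log.error("run %s failed: %s", spec.animal_id or spec.image, err)
            rows.append({"animal_id": spec.animal_id, "group": spec.group_label,
                         "error": f"{type(err).__name__}: {err}"})
            details.append(None)
            continue
        row = res.tbr.to_dict()
        row["error"] = ""
        rows.append(row)
        details.append(res)
        n_ok += 1
    if not rows:
        raise BatchError("empty batch: no runs supplied")
    if n_ok == 0:
        raise BatchError(f"all {len(rows)} runs failed; first error: {rows[0]['error']}")
    table = pd.DataFrame(rows)
    # stable column order even when the first row is an error row
    cols = ["animal_id", "group", "median_target", "median_background",
            "median_norm_ipsi", "median_norm_contra", "rel_ipsi", "rel_contra",
            "tbr", "error"]
    for c in cols:
        if c not in table.columns:
            table[c] = np.nan
    return table[cols], details
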