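# Methods

## The measurement

`ebtbr` quantifies blood-brain-barrier (BBB) disruption *ex vivo* from a
single photographed coronal brain slice of an animal that received
intravenous Evans blue. Evans blue binds serum albumin; the complex cannot
cross an intact BBB, so blue staining of parenchyma marks barrier opening.
Because RGB is additive, the blue channel of the photograph tracks the dye.

The statistic is a **target-to-background ratio (TBR)**. With med(·) the
median blue intensity of a 50 × 50-px square,

```
rel_ipsi   = med(target)     / med(norm_ipsi)
rel_contra = med(background) / med(norm_contra)
TBR        = rel_ipsi / rel_contra
           = med(target) · med(norm_contra) / (med(background) · med(norm_ipsi))
```

where *target* sits under the cranial window (user-picked seed), *background*
is its horizontal mirror in the contralateral hemisphere, and the two *norm*
squares sit near the bottom of the slice, one per hemisphere, well outside
the region of interest. TBR > 1 means ipsilateral dye excess. The method is
semiquantitative: only relative comparisons (against sham animals) are
meaningful, never absolute dye content.

## Pipeline and assumptions

1. **Intensity scale.** The blue plane is kept on the uint16 scale (8-bit
   inputs are promoted by ×257 so 255 ↦ 65535) and stretched linearly so the
   image minimum is 0 and the maximum 65535. Values are rounded to the
   nearest integer. Rescaling the whole image (not only brain pixels) is
   used; since TBR is a ratio of medians this only matters through the
   additive offset of the map, which vanishes when the image minimum comes
   from a near-black dish background. Rescaling makes TBR invariant under
   positive affine changes of illumination, which is the property that lets
   photographs from different sessions be compared. A constant image is
   rejected as degenerate.
2. **Segmentation.** Brain is separated from background by one of three
   per-image filters: an intensity threshold (manual or Otsu), a
   central-difference gradient-magnitude threshold whose enclosing edge band
   is filled, or Canny edge detection followed by contour interpolation and
   filling. The result is a binary mask (1 = brain). The assumption is one
   connected brain per slice photographed on a darker background; the
   largest component is kept in Canny mode and small specks are removed
   everywhere.
3. **Geometry.** The image is cropped to the mask's tight bounding box; the
   upper 20% of the cutout (rounded up) approximates cortex between surface
   and ventricles and is the ROI. The target square is centred on the seed
   (clamped inward at edges); the background square mirrors it about the
   cutout's vertical midline (`col_bg = cols − col_t − side`); the norm
   squares share those columns in a bottom band `margin` pixels above the
   cutout's base. The target position is stored as distances from the
   bounding-box edges, so a placement replays exactly on a re-segmented
   image. Conventions are 0-based (row, col), row 0 on top, half-open square
   extents.
4. **Medians.** Square medians exclude pixels outside the brain mask (their
   near-zero values would drag the median toward zero when a square
   overhangs the brain outline); the exclusion count is logged. A square
   with no brain pixels, or a zero median, aborts that image with an error
   naming the square.
5. **Statistics.** Group comparison uses Kruskal-Wallis ANOVA on ranks
   (tie-corrected H; chi-square approximation, or exact permutation
   enumeration for pooled n ≤ 10), Dunn's post hoc z comparisons on mean
   ranks with Bonferroni adjustment over all pairs (an unadjusted option
   exists), and the Mann-Whitney rank-sum test for two groups (exact U
   distribution when the smaller group has ≤ 8 observations and no ties).
   All tests are two-sided; ties get mid-ranks with variance correction.
   Summaries are median (Q1–Q3).

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| `roi_fraction` | 0.20 | — | upper-cutout share approximating supraventricular cortex |
| `side` | 50 | px | square matched to cranial-window width (~4 mm) and cortical thickness at the native 1040 × 1392 resolution |
| `margin` | 5 | px | gap between norm squares and the cutout's bottom edge |
| `intensity_threshold` | Otsu | uint16 | manual per-image tuning is expected; Otsu is the batch fallback |
| `gradient_threshold` | half of peak | uint16/px | edge-band cut |
| `gradient_sigma` | 0 | px | optional presmoothing before differentiation for noisy images |
| `canny_sigma` | 3 | px | Gaussian scale of the Canny detector |
| `canny_low`, `canny_high` | 0.02, 0.05 | fraction of full range | hysteresis thresholds on the [0, 1]-normalised gradient |
| `closing_radius` | 5 | px | contour-interpolation span (bridges gaps up to ~2× this) |
| `min_object_area` | 64 | px | speck rejection |

## Numerical choices

- "Maximum intensity" of the rescale is 65535, the actual uint16 maximum
  (2^16 would overflow the type).
- Rounding is round-half-to-even via `np.rint`; even-count medians are the
  mean of the two central order statistics.
- Contour interpolation is dilate → fill-holes → erode with a shared disk
  radius. Plain morphological closing of a thin edge curve does not bridge
  even a 3-px gap (the erosion re-opens it); closing the *region* does,
  while restoring the boundary position.
- The gradient filter erodes its filled band by one 4-connected pixel:
  central differences respond one pixel on both sides of a step edge, so
  the filled band overshoots the true region by a one-pixel ring. This makes
  the filter pixel-exact on hard-edged shapes.
- Mirror convention: with even `side` and half-open extents, the seed column
  `cols − c` places the target exactly on the mirror of the target seeded at
  `c`. Consequently swapping which hemisphere is called ipsilateral inverts
  TBR exactly (TBR · TBR′ = 1).
- Degenerate inputs raise typed errors (constant image, empty mask, open
  contour, all-masked square, all-tied sample) rather than returning NaN;
  the batch driver records them per row and continues.

## The phantom generator

Phantoms replace animal data for validation. Each phantom is a bright
ellipse ("brain", default semi-axes 38%/40% of a 1040 × 1392 16-bit frame,
tissue level 30000) on a level-0 background (the near-black dish), left-right
symmetric about the vertical midline. An optional disc in the upper right
hemisphere multiplies the blue channel by `leak_ratio` — multiplicative so
the constructed ratio is exactly the TBR an ideal pipeline recovers. Red and
green are attenuated copies of blue. A global gain/offset models
illumination; additive Gaussian noise (default for noisy studies: 2% of the
dynamic range, σ ≈ 1311) models the sensor, clipped to [0, 65535] after
which values are rounded to uint16. Cohorts jitter geometry (±5%) and tissue
level (±10%) per animal and are fully determined by one seed. The default
cohort mirrors a four-arm design with n = 8/6/7/5 (positive-control leak
1.6 vs three leak-free arms).

Phantom-driven runs use a norm-square margin of 15% of the cutout height
(`synthetic.margin_from_truth`) instead of the 5-px default: a true ellipse
is only a few dozen pixels wide 5 px above its bottom edge, so the default
would place the norm squares mostly on background. Real slices are much
squarer at the base; for them the small margin is appropriate.

What phantoms do *not* emulate: tissue texture, ventricles, vasculature,
asymmetric anatomy, shadows and specular highlights, or segmentation
ambiguity at a soft brain edge. Passing phantom tests therefore demonstrates
the correctness of the algorithmic chain and its invariances, not robustness
to histological variability — per-image threshold tuning remains the user's
responsibility on real data.

## Validation scale and known limitations

Replicated validations (`scripts/acceptance.py`, `tests/test_acceptance.py`)
run single-image properties at the native 1040 × 1392 size and the
replicated cohort study at a 1/5-scale replica (208 × 278 px, square side
10) with 100 replicates per condition, a size chosen so hundreds of
26-animal replicates run comfortably on one CPU; the recovered-ratio
distributions are scale-free because TBR is a ratio of medians.

Known limitations:

- Dunn's test with Bonferroni adjustment over all 6 pairs of the 8/6/7/5
  design has a hard power ceiling: even with complete rank separation of the
  leak group, flagging leak-vs-sham requires the sham arm's mean rank among
  the 18 null observations to fall below ~11.6, which happens in only ~87.5%
  of draws. Detection rates near 85–88% in that design reflect the
  adjustment, not the image pipeline.
- The Kruskal-Wallis chi-square approximation is slightly conservative at
  these group sizes (null rejection ~2–5% at nominal 5%); the exact
  permutation method is available for small pooled samples.
- No physical-unit calibration: pixel squares are not converted to mm²; and
  JPEG input is accepted but discouraged (lossy compression perturbs
  medians).
- The seed ("centre of the cranial window") is user-supplied; the package
  replays it deterministically but does not detect the window itself.
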