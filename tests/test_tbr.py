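"""Square medians, the TBR formula and the batch driver."""

import numpy as np
import pytest
from conftest import make_cutout
from hypothesis import given, settings
from hypothesis import strategies as st

from ebtbr.exceptions import BatchError, DegenerateDataError, PlacementError
from ebtbr.image_io import SliceImage
from ebtbr.roi_geometry import define_roi, mirror_seed, place_squares
from ebtbr.segmentation import FilterConfig
from ebtbr.synthetic import (
    PhantomParams,
    generate_cohort,
    generate_phantom,
    margin_from_truth,
    seed_from_truth,
)
from ebtbr.tbr import RunSpec, assess_image, batch_tbr, compute_tbr, square_median


class TestSquareMedian:
    def test_textbook_even_median(self):
        cut = make_cutout(np.array([[1, 2], [3, 4]], np.float64))
        assert square_median(cut, (0, 0), 2) == 2.5

    def test_constant_patch(self):
        cut = make_cutout(np.full((10, 10), 123.0))
        assert square_median(cut, (2, 3), 5) == 123.0

    def test_out_of_bounds(self):
        cut = make_cutout(np.zeros((10, 10)))
        with pytest.raises(PlacementError):
            square_median(cut, (8, 8), 5)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), side=st.sampled_from([3, 4, 7, 50]))
    def test_matches_full_sort_oracle(self, seed, side):
        rng = np.random.default_rng(seed)
        patch = rng.integers(0, 65536, size=(side, side)).astype(np.float64)
        cut = make_cutout(patch)
        flat = sorted(patch.ravel().tolist())
        n = len(flat)
        oracle = flat[n // 2] if n % 2 else (flat[n // 2 - 1] + flat[n // 2]) / 2.0
        assert square_median(cut, (0, 0), side) == oracle

    def test_background_exclusion(self):
        px = np.array([[0, 0, 9], [0, 7, 9], [5, 7, 9]], np.float64)
        mask = (px > 0).astype(np.uint8)
        cut = make_cutout(px, mask)
        assert square_median(cut, (0, 0), 3) == 7.0  # plain median over 9 pixels
        assert square_median(cut, (0, 0), 3, exclude_background=True) == 8.0

    def test_fully_masked_square_degenerate(self):
        cut = make_cutout(np.ones((4, 4)), np.zeros((4, 4), np.uint8))
        with pytest.raises(DegenerateDataError):
            square_median(cut, (0, 0), 4, exclude_background=True)


def _four_patch_cutout(vt, vb, vni, vnc, rows=200, cols=300, side=20):
    """Cutout whose four square regions have constant values, tissue 1000 elsewhere."""
    px = np.full((rows, cols), 1000.0)
    cut = make_cutout(px)
    sq = place_squares(cut, (30, 220), define_roi(cut), side=side)
    for (r, c), v in zip(
        [sq.target, sq.background, sq.norm_ipsi, sq.norm_contra], [vt, vb, vni, vnc]
    ):
        px[r : r + side, c : c + side] = v
    return cut, sq


class TestComputeTbr:
    def test_full_symmetry_gives_unity(self):
        cut, sq = _four_patch_cutout(800, 800, 800, 800)
        assert compute_tbr(cut, sq).tbr == 1.0

    def test_direct_arithmetic(self):
        cut, sq = _four_patch_cutout(2000, 1000, 500, 500)
        res = compute_tbr(cut, sq, animal_id="a1", group_label="DHC")
        assert res.tbr == 2.0
        assert res.rel_ipsi == 4.0 and res.rel_contra == 2.0
        assert res.animal_id == "a1" and res.group_label == "DHC"

    def test_single_normalizer_variant(self):
        cut, sq = _four_patch_cutout(2000, 1000, 500, 250)
        assert compute_tbr(cut, sq).tbr == 1.0          # per-side normalizers
        assert compute_tbr(cut, sq, single_normalizer=True).tbr == 2.0

    def test_zero_median_names_square(self):
        cut, sq = _four_patch_cutout(2000, 0, 500, 500)
        with pytest.raises(DegenerateDataError, match="background"):
            compute_tbr(cut, sq)

    def test_product_identity_and_scale_invariance(self, rng):
        for _ in range(10):
            vals = rng.uniform(100, 60000, size=4)
            cut, sq = _four_patch_cutout(*vals)
            res = compute_tbr(cut, sq)
            identity = (res.median_target * res.median_norm_contra) / (
                res.median_background * res.median_norm_ipsi
            )
            assert res.tbr == pytest.approx(identity, abs=1e-12)
            k = float(rng.uniform(0.1, 3.0))
            cut2, sq2 = _four_patch_cutout(*(k * vals))
            assert compute_tbr(cut2, sq2).tbr == pytest.approx(res.tbr, rel=1e-12)

    def test_noiseless_phantom_ratio_flat_norms(self):
        """Constructed leak with flat normalizers recovers the ratio to 1e-9."""
        cut, sq = _four_patch_cutout(1500.0, 1000.0, 1000.0, 1000.0)
        assert compute_tbr(cut, sq).tbr == pytest.approx(1.5, abs=1e-9)


class TestPipelineOnPhantoms:
    def test_noiseless_leak_recovered_end_to_end(self, small_params):
        from dataclasses import replace

        for ratio in (1.5, 2.0):
            img, truth = generate_phantom(replace(small_params, leak_ratio=ratio))
            res = assess_image(
                img, seed_from_truth(truth), FilterConfig(mode="intensity"),
                side=10, margin=margin_from_truth(truth),
            )
            assert res.tbr.tbr == pytest.approx(ratio, abs=1e-3)  # rescale rounding

    def test_mirrored_seed_gives_reciprocal_tbr(self, small_params):
        """Swapping which hemisphere is 'ipsilateral' inverts the ratio exactly."""
        from dataclasses import replace

        img, truth = generate_phantom(replace(small_params, leak_ratio=1.5))
        m = margin_from_truth(truth)
        r1 = assess_image(img, seed_from_truth(truth), FilterConfig(mode="intensity"),
                          side=10, margin=m)
        seed_cut = (
            seed_from_truth(truth)[0] - r1.cutout.offset[0],
            seed_from_truth(truth)[1] - r1.cutout.offset[1],
        )
        r2 = assess_image(img, mirror_seed(seed_cut, r1.cutout),
                          FilterConfig(mode="intensity"), side=10, margin=m,
                          seed_space="cutout")
        assert r1.tbr.tbr * r2.tbr.tbr == pytest.approx(1.0, abs=1e-12)


def _cohort_runs(shared, seed=3):
    runs = []
    for i, (img, truth, label) in enumerate(generate_cohort(shared=shared, seed=seed)):
        runs.append(
            RunSpec(image=img, seed_point=seed_from_truth(truth), animal_id=f"a{i:03d}",
                    group_label=label, filter_config=FilterConfig(mode="intensity"))
        )
    return runs


class TestBatch:
    def test_error_rows_are_isolated(self, small_params):
        img, truth = generate_phantom(small_params)
        good = RunSpec(image=img, seed_point=seed_from_truth(truth),
                       animal_id="ok", filter_config=FilterConfig(mode="intensity"))
        bad = RunSpec(image="/does/not/exist.tif", seed_point=(0, 0), animal_id="gone")
        table, details = batch_tbr([good, bad, good],
                                   side=10, margin=margin_from_truth(truth))
        assert len(table) == 3
        assert list(table["error"] == "") == [True, False, True]
        assert details[1] is None
        assert table.loc[1, "error"].startswith("FileNotFoundError")

    def test_determinism_same_input_twice(self, small_params):
        img, truth = generate_phantom(small_params)
        spec = RunSpec(image=img, seed_point=seed_from_truth(truth),
                       filter_config=FilterConfig(mode="intensity"))
        table, _ = batch_tbr([spec, spec], side=10, margin=margin_from_truth(truth))
        assert table.loc[0, "tbr"] == table.loc[1, "tbr"]

    def test_all_failures_raise(self):
        with pytest.raises(BatchError):
            batch_tbr([RunSpec(image="/nope.tif", seed_point=(0, 0))])

    def test_26_phantom_cohort_rows_and_labels(self):
        shared = PhantomParams(rows=208, cols=278, noise_sd=1311.0)
        runs = _cohort_runs(shared)
        table, _ = batch_tbr(runs, side=10, margin=48)
        assert len(table) == 26
        assert table["group"].tolist() == (
            ["DHC"] * 8 + ["sham"] * 6 + ["ET1"] * 7 + ["SD"] * 5
        )
        assert (table["error"] == "").all()


class TestAffineInvariance:
    def test_affine_transform_of_raw_image_preserves_tbr(self):
        params = PhantomParams(rows=208, cols=278, tissue_level=12000.0,
                               leak_ratio=1.5, noise_sd=240.0, seed=11)
        img, truth = generate_phantom(params)
        seed_pt = seed_from_truth(truth)
        m = margin_from_truth(truth)
        base = assess_image(img, seed_pt, FilterConfig(mode="intensity"),
                            side=10, margin=m)
        for a in (0.5, 2.0):
            for b in (0.0, 500.0):
                trans = SliceImage(a * img.pixels.astype(np.float64) + b, 16)
                res = assess_image(trans, seed_pt, FilterConfig(mode="intensity"),
                                   side=10, margin=m)
                assert abs(res.tbr.tbr - base.tbr.tbr) < 1e-6
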