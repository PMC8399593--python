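"""Enhancement chain: channel extraction, CLAHE, patching, splits."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from skimage import exposure

from neoseg.preprocess import (
    DatasetSplit,
    GridError,
    PatchGrid,
    apply_clahe,
    augment_flips,
    crop_background,
    extract_green,
    normalize_patch,
    split_dataset,
    split_patches,
    stitch_patches,
)


class TestExtractGreen:
    def test_selects_middle_channel(self):
        img = np.zeros((2, 2, 3), dtype=np.uint8)
        img[0, 0] = (10, 200, 30)
        assert extract_green(img)[0, 0] == 200

    def test_all_zero(self):
        assert (extract_green(np.zeros((4, 4, 3), dtype=np.uint8)) == 0).all()

    def test_matches_per_pixel_loop_oracle(self, rng):
        img = rng.integers(0, 256, (8, 9, 3)).astype(np.uint8)
        out = extract_green(img)
        for r in range(8):
            for c in range(9):
                assert out[r, c] == img[r, c][1]

    def test_rejects_single_channel(self):
        with pytest.raises(ValueError):
            extract_green(np.zeros((4, 4), dtype=np.uint8))


class TestClahe:
    def test_constant_image_is_fixed_point(self):
        img = np.full((32, 32), 77, dtype=np.uint8)
        np.testing.assert_array_equal(apply_clahe(img), img)

    def test_spreads_a_two_level_raster(self, rng):
        img = np.where(rng.random((64, 64)) > 0.5, 120, 135).astype(np.uint8)
        out = apply_clahe(img, clip_limit=0.02, tile_rows=4, tile_cols=4)
        assert out.std() >= img.std()

    def test_single_tile_high_clip_matches_global_equalization(self, rng):
        img = rng.integers(0, 256, (16, 16)).astype(np.uint8)
        out = apply_clahe(img, clip_limit=1.0, tile_rows=1, tile_cols=1)
        oracle = np.round(exposure.equalize_hist(img, nbins=256) * 255.0)
        assert np.abs(out.astype(float) - oracle).max() <= 2.0

    def test_output_range(self, rng):
        img = rng.integers(0, 256, (64, 64)).astype(np.uint8)
        out = apply_clahe(img)
        assert out.min() >= 0 and out.max() <= 255 and out.dtype == np.uint8

    @pytest.mark.parametrize("kwargs", [dict(clip_limit=0.0), dict(tile_rows=0), dict(tile_cols=-1)])
    def test_invalid_parameters(self, kwargs):
        with pytest.raises(ValueError):
            apply_clahe(np.zeros((16, 16), dtype=np.uint8), **kwargs)


class TestCrop:
    def test_centered_offsets_for_study_geometry(self):
        # 2000x3008 -> 2000x2368 with symmetric background removal: the
        # implied offsets are (0, (3008 - 2368) / 2) = (0, 320).
        src = np.broadcast_to(np.arange(3008, dtype=np.int32), (4, 3008))
        out = crop_background(src, 4, 2368)
        assert out.shape == (4, 2368)
        assert out[0, 0] == 320 and out[0, -1] == 320 + 2368 - 1

    def test_identity_crop(self, rng):
        src = rng.integers(0, 255, (12, 15)).astype(np.uint8)
        np.testing.assert_array_equal(crop_background(src, 12, 15, 0, 0), src)

    def test_window_by_definition(self, rng):
        src = rng.integers(0, 255, (10, 10)).astype(np.uint8)
        np.testing.assert_array_equal(
            crop_background(src, 4, 4, 3, 3), src[3:7, 3:7]
        )

    def test_out_of_bounds_window(self):
        with pytest.raises(ValueError):
            crop_background(np.zeros((10, 10)), 8, 8, 5, 5)


class TestPatchGrids:
    """The patch arithmetic of the study: all printed counts must hold."""

    def test_study_patching_10_per_image(self):
        # 2000x2368 image, 400x1184 patches -> 5x2 grid = 10 patches;
        # 20 images -> 200 patches total.
        grid = PatchGrid(400, 1184, mode="exact")
        assert grid.shape_for(2000, 2368) == (5, 2)
        raster = np.zeros((2000, 2368), dtype=np.uint8)
        assert len(split_patches(raster, grid)) == 10

    def test_comparison_patching_80_per_image(self):
        # 224x224 floor tiling of 2000x2368 -> 8x10 = 80; x20 images = 1600.
        grid = PatchGrid(224, 224, mode="floor")
        assert grid.shape_for(2000, 2368) == (8, 10)

    def test_evaluation_tiling_8_per_patch(self):
        grid = PatchGrid(200, 296, mode="exact")
        assert grid.shape_for(400, 1184) == (2, 4)

    def test_exact_mode_rejects_remainder(self):
        with pytest.raises(GridError):
            PatchGrid(400, 1184, mode="exact").shape_for(2000, 2369)

    def test_row_major_order(self):
        raster = np.arange(4).reshape(2, 2)
        patches = split_patches(raster, PatchGrid(1, 1))
        assert [int(p[0, 0]) for p in patches] == [0, 1, 2, 3]

    def test_stitch_is_row_major_inverse(self):
        patches = [np.array([[v]]) for v in "abcd"]
        out = stitch_patches(patches, PatchGrid(1, 1), 2, 2)
        assert out.tolist() == [["a", "b"], ["c", "d"]]

    def test_stitch_count_mismatch(self):
        with pytest.raises(GridError):
            stitch_patches([np.zeros((1, 1))] * 3, PatchGrid(1, 1), 2, 2)

    @settings(deadline=None, max_examples=25)
    @given(
        n_rows=st.integers(1, 4),
        n_cols=st.integers(1, 4),
        ph=st.integers(1, 7),
        pw=st.integers(1, 7),
        seed=st.integers(0, 2**16),
    )
    def test_split_stitch_round_trip(self, n_rows, n_cols, ph, pw, seed):
        rng = np.random.default_rng(seed)
        raster = rng.integers(0, 256, (n_rows * ph, n_cols * pw)).astype(np.uint8)
        grid = PatchGrid(ph, pw, mode="exact")
        patches = split_patches(raster, grid)
        np.testing.assert_array_equal(
            stitch_patches(patches, grid, n_rows, n_cols), raster
        )

    def test_mask_round_trip_conserves_neo_count(self, rng):
        mask = (rng.random((8, 12)) > 0.7).astype(np.uint8) * 255
        grid = PatchGrid(4, 4)
        patches = split_patches(mask, grid)
        assert sum((p > 0).sum() for p in patches) == (mask > 0).sum()


class TestNormalize:
    def test_endpoints(self):
        out = normalize_patch(np.array([[50, 150]], dtype=np.uint8))
        assert out.tolist() == [[0, 255]]

    def test_full_range_unchanged(self, rng):
        patch = rng.integers(0, 256, (6, 6)).astype(np.uint8)
        patch[0, 0], patch[-1, -1] = 0, 255
        np.testing.assert_array_equal(normalize_patch(patch), patch)

    def test_midpoint_rounds_half_up(self):
        out = normalize_patch(np.array([[10, 20, 30]], dtype=np.uint8))
        assert out.tolist() == [[0, 128, 255]]

    def test_constant_patch_maps_to_zero(self):
        assert (normalize_patch(np.full((3, 3), 99, dtype=np.uint8)) == 0).all()


class TestAugmentFlips:
    def test_triples_and_orders(self, rng):
        patches = [rng.integers(0, 256, (4, 6)).astype(np.uint8) for _ in range(5)]
        masks = [(rng.random((4, 6)) > 0.5).astype(np.uint8) * 255 for _ in range(5)]
        out_p, out_m = augment_flips(patches, masks)
        assert len(out_p) == len(out_m) == 15
        np.testing.assert_array_equal(out_p[5], patches[0][:, ::-1])
        np.testing.assert_array_equal(out_p[10], patches[0][::-1, :])
        np.testing.assert_array_equal(out_m[5], masks[0][:, ::-1])

    def test_symmetric_patch_gives_identical_copies(self):
        sym = np.ones((4, 4), dtype=np.uint8) * 7
        out_p, _ = augment_flips([sym], [sym])
        for p in out_p:
            np.testing.assert_array_equal(p, sym)

    def test_neo_count_conserved_per_flip(self, rng):
        mask = (rng.random((6, 8)) > 0.6).astype(np.uint8) * 255
        _, out_m = augment_flips([mask.copy()], [mask])
        assert all((m > 0).sum() == (mask > 0).sum() for m in out_m)

    def test_misaligned_lists_rejected(self):
        with pytest.raises(ValueError):
            augment_flips([np.zeros((2, 2))], [])


class TestSplitDataset:
    def test_study_proportions_200_to_100_50_50(self):
        ds = split_dataset(200, (0.5, 0.25, 0.25), seed=3)
        assert (len(ds.train), len(ds.validation), len(ds.test)) == (100, 50, 50)

    def test_partition_is_disjoint_and_exhaustive(self):
        ds = split_dataset(37, (0.5, 0.25, 0.25), seed=5)
        all_items = sorted(ds.train + ds.validation + ds.test)
        assert all_items == list(range(37))

    def test_same_seed_same_partition(self):
        a = split_dataset(50, seed=9)
        b = split_dataset(50, seed=9)
        assert a == b

    def test_four_items(self):
        ds = split_dataset(4, (0.5, 0.25, 0.25), seed=0)
        assert (len(ds.train), len(ds.validation), len(ds.test)) == (2, 1, 1)

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError):
            split_dataset(10, (0.5, 0.3, 0.3), seed=0)
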