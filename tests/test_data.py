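"""Tiling, split allocation and augmentation bookkeeping."""

import numpy as np
import pytest

from dsca.augment import AugSpec, apply_augmentation, augment_training_set, draw_params
from dsca.data import (TileRecord, allocate_split, assign_splits,
                       compute_normalization, read_manifest, stitch_tiles,
                       tile_scene, write_manifest)
from dsca.errors import DataError, TilingError


def _random_scene(rng, h, w):
    image = rng.integers(0, 256, size=(h, w, 3), dtype=np.uint8)
    mask = (rng.random((h, w)) < 0.3).astype(np.uint8)
    return image, mask


class TestTiling:
    def test_4096_scene_yields_64_tiles(self, rng):
        image, mask = _random_scene(rng, 4096, 4096)
        records = tile_scene(image, mask, 512, "s0")
        assert len(records) == 64
        assert {(r.row, r.col) for r in records} == {(i, j) for i in range(8) for j in range(8)}

    def test_single_tile_is_identity(self, rng):
        image, mask = _random_scene(rng, 512, 512)
        (rec,) = tile_scene(image, mask, 512, "s0")
        np.testing.assert_array_equal(rec.load_image(), image)
        np.testing.assert_array_equal(rec.load_mask(), mask)

    def test_rectangular_grid(self, rng):
        image, mask = _random_scene(rng, 1024, 1536)
        records = tile_scene(image, mask, 512, "s0")
        assert len(records) == 6
        assert max(r.row for r in records) == 1 and max(r.col for r in records) == 2

    def test_non_divisible_scene_rejected(self, rng):
        image, mask = _random_scene(rng, 1000, 1024)
        with pytest.raises(TilingError, match="not divisible"):
            tile_scene(image, mask, 512)

    def test_round_trip_is_exact(self, rng):
        image, mask = _random_scene(rng, 256, 384)
        records = tile_scene(image, mask, 128, "s0")
        image2, mask2 = stitch_tiles(records)
        np.testing.assert_array_equal(image2, image)
        np.testing.assert_array_equal(mask2, mask)


class TestSplitAllocation:
    def test_single_scene_largest_remainder_tie_break(self):
        plan = allocate_split([64], seed=0)
        assert plan.per_scene == [(45, 10, 9)]

    def test_twenty_scene_global_totals(self):
        plan = allocate_split([64] * 20, seed=0)
        assert plan.totals == (896, 192, 192)
        assert all(sum(s) == 64 for s in plan.per_scene)

    def test_degenerate_all_train(self):
        assert allocate_split([10, 20], fractions=(1.0, 0.0, 0.0)).totals == (30, 0, 0)

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            allocate_split([64], fractions=(0.5, 0.3, 0.1))

    @pytest.mark.parametrize("seed", [0, 1, 17])
    def test_totals_seed_invariant_plan_seed_deterministic(self, seed):
        a = allocate_split([64] * 5, seed=seed)
        b = allocate_split([64] * 5, seed=seed)
        assert a.per_scene == b.per_scene
        assert a.totals == allocate_split([64] * 5, seed=seed + 100).totals

    def test_assignment_conserves_and_separates(self, rng):
        image, mask = _random_scene(rng, 256, 256)
        records = tile_scene(image, mask, 64, "s0")
        plan = allocate_split([len(records)], seed=3)
        assign_splits(records, plan, ["s0"], seed=3)
        counts = {s: sum(1 for r in records if r.split == s)
                  for s in ("train", "val", "test")}
        assert (counts["train"], counts["val"], counts["test"]) == plan.per_scene[0]
        assert all(r.split is not None for r in records)


class TestAugmentation:
    @pytest.fixture()
    def tile(self, rng):
        image, mask = _random_scene(rng, 64, 64)
        rec = tile_scene(image, mask, 64, "s0")[0]
        rec.split = "train"
        return rec

    def test_output_counts(self, tile):
        out = augment_training_set([tile], AugSpec(copies_per_original=5, seed=1))
        assert len(out) == 6
        assert sum(1 for r in out if r.aug_index == 0) == 1
        assert sorted(r.aug_index for r in out) == [0, 1, 2, 3, 4, 5]

    def test_zero_copies_is_identity(self, tile):
        out = augment_training_set([tile], AugSpec(copies_per_original=0))
        assert len(out) == 1 and out[0] is tile

    def test_bit_identical_under_seed(self, tile):
        spec = AugSpec(copies_per_original=2, seed=9)
        a = [r for r in augment_training_set([tile], spec) if r.aug_index > 0]
        b = [r for r in augment_training_set([tile], spec) if r.aug_index > 0]
        for ra, rb in zip(a, b):
            np.testing.assert_array_equal(ra.load_image(), rb.load_image())
            np.testing.assert_array_equal(ra.load_mask(), rb.load_mask())

    def test_masks_stay_binary_and_images_uint8(self, tile):
        spec = AugSpec(copies_per_original=3, seed=4)
        for rec in augment_training_set([tile], spec):
            img, msk = rec.load_image(), rec.load_mask()
            assert img.dtype == np.uint8 and img.shape == (64, 64, 3)
            assert set(np.unique(msk)).issubset({0, 1})

    def test_refuses_non_train_tiles(self, tile):
        tile.split = "val"
        with pytest.raises(DataError, match="training tiles"):
            augment_training_set([tile], AugSpec())

    @pytest.mark.parametrize("hflip,vflip,angle", [
        (True, False, 0.0), (False, True, 0.0), (True, True, 0.0),
        (False, False, 90.0), (False, False, 180.0), (False, False, 270.0)])
    def test_flips_and_quarter_turns_preserve_foreground(self, tile, hflip, vflip, angle):
        params = {"angle_deg": angle, "scale": 1.0, "hflip": hflip, "vflip": vflip,
                  "brightness": 0.0, "contrast": 0.0, "hue_shift": 0.0,
                  "sat_shift": 0.0, "val_shift": 0.0, "blur_kernel": 3,
                  "noise_var": 0.0, "noise_seed": 0}
        _, msk = apply_augmentation(tile.load_image(), tile.load_mask(), params)
        assert int(msk.sum()) == int(tile.load_mask().sum())

    def test_parameters_differ_across_copies(self, tile):
        spec = AugSpec(seed=2)
        p1 = draw_params(spec, tile, 1)
        p2 = draw_params(spec, tile, 2)
        assert p1 != p2


class TestManifest:
    def test_round_trip(self, rng, tmp_path):
        image, mask = _random_scene(rng, 128, 128)
        records = tile_scene(image, mask, 64, "s0")
        for r in records:
            r.split = "train"
            r.image_path = "x.png"
            r.mask_path = "y.png"
        path = tmp_path / "manifest.csv"
        write_manifest(records, path)
        loaded = read_manifest(path)
        assert [(r.scene_id, r.row, r.col, r.split, r.aug_index) for r in loaded] \
            == [(r.scene_id, r.row, r.col, r.split, r.aug_index) for r in records]

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("scene_id,row\ns,1\n")
        with pytest.raises(DataError, match="missing columns"):
            read_manifest(path)


def test_normalization_statistics(rng):
    image = np.full((64, 64, 3), 128, dtype=np.uint8)
    mask = np.zeros((64, 64), dtype=np.uint8)
    rec = tile_scene(image, mask, 64, "s")[0]
    mean, std = compute_normalization([rec])
    np.testing.assert_allclose(mean, 128 / 255, atol=1e-6)
    assert np.all(std > 0)
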