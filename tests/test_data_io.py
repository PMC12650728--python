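"""Dataset loading, splitting, and the three-stage augmentation protocol."""

import json

import numpy as np
import pytest
from PIL import Image

from snakeseg.data_io import (
    AugmentationConfig,
    Sample,
    augment,
    clahe,
    flip_sample,
    load_dataset,
    rotate_sample,
    split_dataset,
    write_image,
    write_mask,
)


def make_sample(rng, size=32):
    img = rng.random((size, size)).astype(np.float32)
    mask = (rng.random((size, size)) > 0.7).astype(np.uint8)
    return Sample(image=img, mask=mask, id="t")


class TestLoadDataset:
    def test_png_pairs_round_trip(self, tmp_path, rng):
        (tmp_path / "images").mkdir()
        (tmp_path / "masks").mkdir()
        for i in range(3):
            write_image(tmp_path / "images" / f"case{i}.png", rng.random((16, 16)))
            write_mask(tmp_path / "masks" / f"case{i}.png", rng.random((16, 16)) > 0.5)
        samples = load_dataset(tmp_path)
        assert len(samples) == 3
        for s in samples:
            assert s.image.shape == s.mask.shape == (16, 16)
            assert s.image.min() >= 0.0 and s.image.max() <= 1.0

    def test_255_valued_masks_binarized(self, tmp_path):
        (tmp_path / "images").mkdir()
        (tmp_path / "masks").mkdir()
        write_image(tmp_path / "images" / "a.png", np.zeros((8, 8)))
        Image.fromarray((np.eye(8) * 255).astype(np.uint8)).save(tmp_path / "masks" / "a.png")
        (s,) = load_dataset(tmp_path)
        assert set(np.unique(s.mask)) <= {0, 1}
        np.testing.assert_array_equal(s.mask, np.eye(8))

    def test_unmatched_image_skipped_with_warning(self, tmp_path, rng, caplog):
        (tmp_path / "images").mkdir()
        (tmp_path / "masks").mkdir()
        write_image(tmp_path / "images" / "a.png", rng.random((8, 8)))
        write_image(tmp_path / "images" / "b.png", rng.random((8, 8)))
        write_mask(tmp_path / "masks" / "a.png", np.eye(8) > 0)
        samples = load_dataset(tmp_path)
        assert [s.id for s in samples] == ["a"]

    def test_empty_directory_errors(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_dataset(tmp_path)

    def test_polygon_square_rasterizes_exactly(self, tmp_path, rng):
        (tmp_path / "images").mkdir()
        write_image(tmp_path / "images" / "poly.png", rng.random((8, 8)))
        # square around pixel centers (3,3),(3,4),(4,3),(4,4); vertices are
        # (x, y) with pixel centers at integers
        ann = {
            "images": [{"id": 1, "file_name": "poly.png"}],
            "annotations": [
                {"image_id": 1, "segmentation": [[2.6, 2.6, 4.4, 2.6, 4.4, 4.4, 2.6, 4.4]], "category_id": 1}
            ],
        }
        (tmp_path / "annotations.json").write_text(json.dumps(ann))
        (s,) = load_dataset(tmp_path)
        want = np.zeros((8, 8), np.uint8)
        want[3:5, 3:5] = 1
        np.testing.assert_array_equal(s.mask, want)


class TestSplitDataset:
    def test_canonical_ratio(self):
        tr, va, te = split_dataset(list(range(1500)), seed=0)
        assert (len(tr), len(va), len(te)) == (1000, 200, 300)

    def test_proportional_scaling(self):
        tr, va, te = split_dataset(list(range(15)), seed=0)
        assert (len(tr), len(va), len(te)) == (10, 2, 3)

    def test_partition_property(self):
        items = list(range(47))
        tr, va, te = split_dataset(items, seed=5)
        combined = sorted(tr + va + te)
        assert combined == items
        assert not (set(tr) & set(va) or set(tr) & set(te) or set(va) & set(te))

    def test_seed_reproducibility(self):
        a = split_dataset(list(range(30)), seed=9)
        b = split_dataset(list(range(30)), seed=9)
        assert a == b

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            split_dataset([1, 2], seed=0)


class TestClahe:
    def test_constant_image_fixed_point(self):
        img = np.full((32, 32), 0.4, dtype=np.float32)
        np.testing.assert_array_equal(clahe(img), img)

    def test_output_stays_in_unit_range(self, rng):
        for _ in range(5):
            out = clahe(rng.random((32, 32)).astype(np.float32))
            assert out.min() >= 0.0 and out.max() <= 1.0

    def test_single_tile_matches_global_equalization(self):
        """With one tile and no clipping, CLAHE reduces to plain histogram
        equalization of the whole image (cross-checked against the library's
        global equalizer)."""
        from skimage import exposure

        rng = np.random.default_rng(0)
        img = rng.beta(2, 5, (64, 64)).astype(np.float32)
        ours = clahe(img, clip_limit=1.0, tile_grid=(1, 1))
        ref = exposure.equalize_hist(img)
        # same monotone ranking; values agree up to binning differences
        assert np.corrcoef(ours.ravel(), ref.ravel())[0, 1] > 0.99
        assert np.abs(ours - ref).mean() < 0.05


class TestAugment:
    def test_horizontal_flip_moves_mask_exactly(self, rng):
        s = make_sample(rng)
        flipped = flip_sample(s, axis=1)
        np.testing.assert_array_equal(flipped.mask, s.mask[:, ::-1])
        np.testing.assert_array_equal(flipped.image, s.image[:, ::-1])

    def test_photometric_stages_leave_mask_bitwise_unchanged(self, rng):
        s = make_sample(rng)
        cfg = AugmentationConfig(with_geometric=False, crop_size=32)
        out = augment(s, cfg, np.random.default_rng(0))
        np.testing.assert_array_equal(out.mask, s.mask)

    def test_right_angle_rotation_matches_hand_rotated_mask(self):
        mask = np.zeros((6, 6), np.uint8)
        mask[1:5, 2] = 1  # vertical bar
        mask[4, 2:4] = 1  # foot of an L
        s = Sample(image=mask.astype(np.float32), mask=mask, id="L")
        rot = rotate_sample(s, 90)
        np.testing.assert_array_equal(rot.mask, np.rot90(mask))

    def test_geometric_stage_keeps_mask_binary_and_shapes_aligned(self, rng):
        s = make_sample(rng, size=48)
        cfg = AugmentationConfig(crop_size=32)
        for i in range(5):
            out = augment(s, cfg, np.random.default_rng(i))
            assert out.image.shape == out.mask.shape == (32, 32)
            assert set(np.unique(out.mask)) <= {0, 1}

    def test_fixed_rng_state_is_bitwise_reproducible(self, rng):
        s = make_sample(rng, size=48)
        cfg = AugmentationConfig(crop_size=32)
        a = augment(s, cfg, np.random.default_rng(42))
        b = augment(s, cfg, np.random.default_rng(42))
        np.testing.assert_array_equal(a.image, b.image)
        np.testing.assert_array_equal(a.mask, b.mask)

    def test_crop_larger_than_image_rejected(self, rng):
        s = make_sample(rng, size=16)
        cfg = AugmentationConfig(crop_size=64, with_geometric=False)
        out = augment(s, cfg, np.random.default_rng(0))  # no crop applied
        assert out.image.shape == (16, 16)


def test_sample_shape_agreement_enforced():
    with pytest.raises(Exception):
        Sample(image=np.zeros((4, 4)), mask=np.zeros((5, 5), np.uint8), id="bad")
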