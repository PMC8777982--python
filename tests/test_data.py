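"""Catalog IO, split schemes, and flip/translation augmentation."""

import numpy as np
import pytest
from PIL import Image

from vesselseg.data import (SamplePair, augment, drive_augmentation_grid,
                            load_catalog, load_pair, make_splits,
                            read_manifest, write_manifest, write_mask_png)
from vesselseg.exceptions import AugmentationError, InputError, SplitError


def _write_png(path, arr):
    Image.fromarray(arr).save(path)


@pytest.fixture()
def disk_pair(tmp_path):
    rng = np.random.default_rng(0)
    img = rng.integers(0, 256, size=(20, 24, 3), dtype=np.uint8)
    mask = (rng.random((20, 24)) < 0.3).astype(np.uint8) * 255
    _write_png(tmp_path / "img.png", img)
    _write_png(tmp_path / "mask.png", mask)
    return tmp_path / "img.png", tmp_path / "mask.png", img, mask


class TestLoadPair:
    def test_round_trip(self, disk_pair):
        ip, mp, img, mask = disk_pair
        pair = load_pair(ip, mp)
        np.testing.assert_array_equal(pair.image, img)
        np.testing.assert_array_equal(pair.mask, (mask >= 128).astype(np.uint8))

    def test_all_white_mask_is_all_vessel(self, tmp_path):
        _write_png(tmp_path / "i.png", np.zeros((5, 5, 3), np.uint8))
        _write_png(tmp_path / "m.png", np.full((5, 5), 255, np.uint8))
        assert load_pair(tmp_path / "i.png", tmp_path / "m.png").mask.all()

    def test_threshold_is_inclusive(self, tmp_path):
        m = np.array([[0, 128, 255]], np.uint8)
        _write_png(tmp_path / "i.png", np.zeros((1, 3, 3), np.uint8))
        _write_png(tmp_path / "m.png", m)
        pair = load_pair(tmp_path / "i.png", tmp_path / "m.png", binarize_threshold=128)
        np.testing.assert_array_equal(pair.mask[0], [0, 1, 1])

    def test_gif_mask_supported(self, tmp_path):
        """DRIVE ships GIF annotation masks."""
        _write_png(tmp_path / "i.png", np.zeros((4, 4, 3), np.uint8))
        Image.fromarray(np.full((4, 4), 255, np.uint8)).save(tmp_path / "m.gif")
        assert load_pair(tmp_path / "i.png", tmp_path / "m.gif").mask.all()

    def test_drive_sized_pair_pixel_count(self, tmp_path):
        _write_png(tmp_path / "i.png", np.zeros((584, 565, 3), np.uint8))
        _write_png(tmp_path / "m.png", np.zeros((584, 565), np.uint8))
        assert load_pair(tmp_path / "i.png", tmp_path / "m.png").n_pixels == 329_960

    def test_dimension_mismatch_raises_with_path(self, tmp_path):
        _write_png(tmp_path / "i.png", np.zeros((4, 4, 3), np.uint8))
        _write_png(tmp_path / "m.png", np.zeros((5, 4), np.uint8))
        with pytest.raises(InputError, match="i.png"):
            load_pair(tmp_path / "i.png", tmp_path / "m.png")

    def test_unreadable_file_raises_with_path(self, tmp_path):
        (tmp_path / "bad.png").write_text("not a png")
        _write_png(tmp_path / "m.png", np.zeros((4, 4), np.uint8))
        with pytest.raises(InputError, match="bad.png"):
            load_pair(tmp_path / "bad.png", tmp_path / "m.png")


class TestManifest:
    def test_write_read_load(self, tmp_path, disk_pair):
        rows = [{"id": "a", "image": "img.png", "mask": "mask.png", "split": "train"}]
        write_manifest(rows, tmp_path / "manifest.tsv")
        assert read_manifest(tmp_path / "manifest.tsv") == rows
        pairs, tags = load_catalog(tmp_path / "manifest.tsv")
        assert pairs[0].id == "a" and tags == {"a": "train"}

    def test_bad_header_rejected(self, tmp_path):
        (tmp_path / "m.tsv").write_text("foo\tbar\n1\t2\n")
        with pytest.raises(InputError, match="header"):
            read_manifest(tmp_path / "m.tsv")


class TestSplits:
    def test_leave_one_out_over_20(self):
        ids = [f"s{i}" for i in range(20)]
        scheme = make_splits(ids, "leave_one_out")
        assert len(scheme.experiments) == 20
        for train, test in scheme.experiments:
            assert len(train) == 19 and len(test) == 1
            assert set(train) | set(test) == set(ids)
            assert not set(train) & set(test)

    def test_two_fold_over_28(self):
        ids = [f"s{i}" for i in range(28)]
        scheme = make_splits(ids, "two_fold")
        assert len(scheme.experiments) == 2
        (a_tr, a_te), (b_tr, b_te) = scheme.experiments
        assert len(a_tr) == len(a_te) == 14
        assert a_tr == b_te and a_te == b_tr

    def test_fixed_uses_provider_tags(self):
        tags = {"a": "train", "b": "test"}
        scheme = make_splits(["a", "b"], "fixed", tags)
        assert scheme.experiments == [(["a"], ["b"])]

    def test_degenerate_cases_rejected(self):
        with pytest.raises(SplitError):
            make_splits(["only"], "leave_one_out")
        with pytest.raises(SplitError):
            make_splits(["a", "b", "c"], "two_fold")
        with pytest.raises(SplitError):
            make_splits([], "fixed")


class TestAugment:
    @pytest.fixture()
    def pair(self):
        rng = np.random.default_rng(1)
        img = rng.integers(0, 256, size=(64, 64, 3), dtype=np.uint8)
        mask = (rng.random((64, 64)) < 0.1).astype(np.uint8)
        return SamplePair(id="p", image=img, mask=mask)

    def test_double_horizontal_flip_is_identity(self, pair):
        once = augment([pair], flips=("h",))
        twice = augment([p for p in once if p.id != "p"], flips=("h",))
        back = [p for p in twice if p.id.count("~h~") == 2][0]
        np.testing.assert_array_equal(back.image, pair.image)
        np.testing.assert_array_equal(back.mask, pair.mask)

    def test_flips_conserve_vessel_count(self, pair):
        for out in augment([pair], flips=("none", "h", "v", "hv")):
            assert out.mask.sum() == pair.mask.sum()
            assert out.mask.shape == pair.mask.shape

    def test_drive_grid_expands_20_to_3840(self, pair):
        grid = drive_augmentation_grid()
        assert len(grid["flips"]) * len(grid["translations"]) == 192
        pairs = [SamplePair(id=f"p{i}", image=pair.image, mask=pair.mask)
                 for i in range(20)]
        out = augment(pairs, **grid)
        assert len(out) == 3840

    def test_translation_moves_and_fills_background(self, pair):
        (moved,) = [p for p in augment([pair], translations=((3, 2),))
                    if p.id != "p"]
        assert moved.mask[:2].sum() == 0 and (moved.image[:2] == 0).all()
        np.testing.assert_array_equal(moved.mask[2:, 3:], pair.mask[:-2, :-3])

    def test_out_of_bounds_translation_rejected(self, pair):
        with pytest.raises(AugmentationError):
            augment([pair], translations=((40, 0),))

    def test_augmentation_is_deterministic(self, pair):
        grid = {"flips": ("none", "v"), "translations": ((0, 0), (4, -4))}
        a = augment([pair], **grid)
        b = augment([pair], **grid)
        for x, y in zip(a, b):
            assert x.id == y.id
            np.testing.assert_array_equal(x.image, y.image)


def test_write_mask_png_uses_255_for_vessel(tmp_path):
    import imageio.v3 as iio
    write_mask_png(np.array([[1, 0]], np.uint8), tmp_path / "m.png")
    np.testing.assert_array_equal(iio.imread(tmp_path / "m.png"), [[255, 0]])
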