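import numpy as np
import pytest
from PIL import Image

from histotex.image_io import (
    ImageFormatError,
    RGBImage,
    extract_rois,
    load_image,
    reduce_resolution,
    save_image,
)


def _random_image(rng, rows, cols):
    return RGBImage(pixels=rng.integers(0, 256, size=(rows, cols, 3), dtype=np.uint8))


class TestLoadImage:
    def test_full_size_bmp(self, rng, tmp_path):
        path = tmp_path / "full.bmp"
        save_image(_random_image(rng, 512, 680), path)
        image = load_image(path)
        assert image.pixels.shape == (512, 680, 3)

    def test_all_zero_png(self, tmp_path):
        path = tmp_path / "zeros.png"
        Image.fromarray(np.zeros((4, 4, 3), dtype=np.uint8)).save(path)
        image = load_image(path)
        assert (image.pixels == 0).all()

    @pytest.mark.parametrize("ext", ["png", "bmp"])
    def test_round_trip(self, rng, tmp_path, ext):
        original = _random_image(rng, 8, 8)
        path = tmp_path / f"rt.{ext}"
        save_image(original, path)
        assert (load_image(path).pixels == original.pixels).all()

    def test_rejects_non_rgb(self, tmp_path):
        path = tmp_path / "grey.png"
        Image.fromarray(np.zeros((4, 4), dtype=np.uint8), mode="L").save(path)
        with pytest.raises(ImageFormatError, match="mode"):
            load_image(path)

    def test_rejects_unreadable(self, tmp_path):
        path = tmp_path / "junk.png"
        path.write_bytes(b"not an image")
        with pytest.raises(ImageFormatError):
            load_image(path)


class TestReduceResolution:
    def test_half_dimensions(self, rng):
        out = reduce_resolution(_random_image(rng, 512, 680), 2)
        assert (out.rows, out.columns) == (256, 340)
        assert out.resolution == "half"

    def test_quarter_dimensions(self, rng):
        out = reduce_resolution(_random_image(rng, 512, 680), 4)
        assert (out.rows, out.columns) == (128, 170)
        assert out.resolution == "quarter"

    def test_factor_one_identity(self, rng):
        image = _random_image(rng, 16, 16)
        assert (reduce_resolution(image, 1).pixels == image.pixels).all()

    def test_block_mean_by_hand(self):
        block = np.zeros((2, 2, 3), dtype=np.uint8)
        block[:, :, 0] = [[10, 20], [30, 40]]
        out = reduce_resolution(RGBImage(pixels=block), 2)
        assert out.pixels[0, 0, 0] == 25

    def test_non_divisible_raises(self, rng):
        with pytest.raises(ValueError, match="divisible"):
            reduce_resolution(_random_image(rng, 17, 20), 2)

    def test_twice_half_close_to_quarter(self, rng):
        image = _random_image(rng, 64, 64)
        twice = reduce_resolution(reduce_resolution(image, 2), 2)
        quarter = reduce_resolution(image, 4)
        diff = np.abs(twice.pixels.astype(int) - quarter.pixels.astype(int))
        assert diff.max() <= 1


class TestExtractRois:
    def test_cohort_roi_counts(self, rng):
        images = [_random_image(rng, 64, 64) for _ in range(12)]
        for image, label in zip(images, ["F"] * 7 + ["C"] * 5):
            image.label = label
        rois = [roi for image in images for roi in extract_rois(image, margin=0.0)]
        labels = [roi.label for roi in rois]
        assert labels.count("F") == 28
        assert labels.count("C") == 20

    def test_exact_partition(self, rng):
        image = _random_image(rng, 100, 100)
        rois = extract_rois(image, margin=0.0)
        assert all(roi.pixels.shape == (50, 50, 3) for roi in rois)
        top = np.concatenate([rois[0].pixels, rois[1].pixels], axis=1)
        bottom = np.concatenate([rois[2].pixels, rois[3].pixels], axis=1)
        reassembled = np.concatenate([top, bottom], axis=0)
        assert (reassembled == image.pixels).all()

    def test_odd_dimensions_drop_far_edge(self, rng):
        rois = extract_rois(_random_image(rng, 101, 101), margin=0.0)
        assert all(roi.pixels.shape == (50, 50, 3) for roi in rois)

    def test_too_small_raises(self, rng):
        with pytest.raises(ValueError, match="too small"):
            extract_rois(_random_image(rng, 20, 20), margin=0.0)

    def test_margin_trims_borders(self, rng):
        image = _random_image(rng, 100, 100)
        rois = extract_rois(image, margin=0.1)
        assert all(roi.pixels.shape == (40, 40, 3) for roi in rois)
        assert (rois[0].pixels == image.pixels[10:50, 10:50]).all()
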