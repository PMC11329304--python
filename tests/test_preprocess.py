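"""Preprocessing pipeline: orientation, cropping, normalization, geometry
round trips and augmentation."""

import numpy as np
import pytest
from scipy import ndimage

from mammoseg.phantom import PhantomConfig, generate_phantom
from mammoseg.preprocess import (
    augment_pair, binarize, compose_three_channel, crop_breast_region,
    enhance_clahe, orient_flip, pad_to_square, preprocess,
    preprocess_to_nspace, restore_to_original, truncate_normalize, CropRecord)


def half_disc(side=100, on_right=False):
    rr, cc = np.mgrid[0:side, 0:side]
    x = (side - 1 - cc) if on_right else cc
    return (((rr - side / 2) / (0.45 * side)) ** 2 +
            (x / (0.7 * side)) ** 2 <= 1).astype(float) * 0.8


class TestOrientFlip:
    def test_right_posed_breast_is_mirrored(self):
        img = half_disc(on_right=True)
        out, _, flipped = orient_flip(img)
        assert flipped
        fg = out > 0.4
        assert np.mean(np.nonzero(fg)[1]) < img.shape[1] / 2

    def test_left_posed_breast_unchanged(self):
        img = half_disc(on_right=False)
        out, _, flipped = orient_flip(img)
        assert not flipped
        assert np.array_equal(out, img)

    def test_idempotent(self):
        img = half_disc(on_right=True)
        once, _, _ = orient_flip(img)
        twice, _, flipped2 = orient_flip(once)
        assert not flipped2
        assert np.array_equal(once, twice)

    def test_all_zero_passes_through(self):
        img = np.zeros((10, 10))
        out, _, flipped = orient_flip(img)
        assert not flipped and np.array_equal(out, img)


class TestCropBreastRegion:
    def test_bright_rectangle_bounding_box(self):
        img = np.zeros((120, 80))
        img[10:100, 5:50] = 1.0
        _, box = crop_breast_region(img)
        assert box == (10, 5, 100, 50)

    def test_full_frame_foreground(self):
        img = np.zeros((30, 30))
        img[1:, :] = 1.0  # Otsu needs two classes; one background row
        cropped, box = crop_breast_region(img)
        assert box == (1, 0, 30, 30)

    def test_largest_component_wins(self):
        img = np.zeros((100, 100))
        img[10:60, 10:20] = 1.0   # 500 px
        img[80:84, 80:85] = 1.0   # 20 px
        _, box = crop_breast_region(img)
        assert box == (10, 10, 60, 20)

    def test_empty_image_raises(self):
        with pytest.raises(ValueError):
            crop_breast_region(np.zeros((10, 10)))


class TestPadToSquare:
    def test_tall_image_padded_right(self):
        img = np.ones((100, 60))
        out, _, pad = pad_to_square(img)
        assert out.shape == (100, 100)
        assert pad == (0, 40)
        assert np.all(out[:, 60:] == 0)

    def test_square_unchanged(self):
        img = np.ones((50, 50))
        out, _, pad = pad_to_square(img)
        assert pad == (0, 0) and np.array_equal(out, img)

    def test_mask_follows_geometry(self):
        img = np.ones((40, 30))
        mask = np.ones((40, 30), dtype=np.uint8)
        _, m, _ = pad_to_square(img, mask)
        assert m.shape == (40, 40)
        assert m[:, 30:].sum() == 0


class TestTruncateNormalize:
    def test_linear_interpolation_percentiles(self):
        # breast pixels take 100 distinct values 1..100: p5 = 5.95, p99 = 99.01
        img = np.zeros((10, 20))
        img[:, 10:] = np.arange(1, 101).reshape(10, 10)
        region = img > 0
        out = truncate_normalize(img, region)
        p5, p99 = 5.95, 99.01
        assert np.isclose(out[9, 19], 1.0)  # value 100 -> clipped to p99 -> 1
        assert np.isclose(out[0, 10], 0.0)  # value 1 <= p5 -> 0
        expected = (50 - p5) / (p99 - p5)
        row, col = 4, 19  # holds value 50
        assert img[row, col] == 50
        assert np.isclose(out[row, col], expected)

    def test_constant_region_degenerates_to_zero(self):
        img = np.full((5, 5), 0.7)
        out = truncate_normalize(img, np.ones((5, 5), bool))
        assert np.all(out == 0)

    def test_output_spans_unit_interval(self, rng):
        img = rng.uniform(0, 1, (32, 32))
        out = truncate_normalize(img, np.ones_like(img, bool))
        assert np.isclose(out.min(), 0.0) and np.isclose(out.max(), 1.0)

    def test_empty_region_raises(self):
        with pytest.raises(ValueError):
            truncate_normalize(np.ones((4, 4)), np.zeros((4, 4), bool))


class TestClahe:
    def test_constant_image_unchanged(self):
        img = np.full((64, 64), 0.5)
        assert np.array_equal(enhance_clahe(img, 0.01), img)

    def test_output_in_unit_interval(self, rng):
        img = rng.uniform(0.4, 0.6, (64, 64))
        out = enhance_clahe(img, 0.02)
        assert out.min() >= 0 and out.max() <= 1

    def test_contrast_increases_on_low_contrast_texture(self):
        s = generate_phantom(PhantomConfig(image_size=128, n_masses=1, seed=4))
        img = 0.4 + 0.2 * s.image  # compress contrast
        out = enhance_clahe(img, 0.02)
        assert out.std() >= img.std()

    def test_nonpositive_clip_rejected(self):
        with pytest.raises(ValueError):
            enhance_clahe(np.zeros((8, 8)), 0.0)


def test_three_channel_composition(rng):
    norm = rng.uniform(0, 1, (40, 40))
    out = compose_three_channel(norm)
    assert out.shape == (40, 40, 3)
    assert np.array_equal(out[..., 0], norm)
    assert np.array_equal(out, compose_three_channel(norm))


class TestPreprocessPipeline:
    @pytest.mark.parametrize("model_size", [128, 64])
    def test_output_shapes(self, phantom_sample, model_size):
        three, mask, rec = preprocess(phantom_sample.image, phantom_sample.mask,
                                      model_size=model_size)
        assert three.shape == (model_size, model_size, 3)
        assert mask.shape == (model_size, model_size)
        assert set(np.unique(mask)) <= {0, 1}
        assert three.min() >= 0 and three.max() <= 1
        assert rec.model_size == model_size

    def test_restore_shape_matches_original(self, phantom_sample):
        _, mask, rec = preprocess(phantom_sample.image, phantom_sample.mask,
                                  model_size=128)
        restored = restore_to_original(mask.astype(float), rec)
        assert restored.shape == phantom_sample.image.shape

    def test_nspace_invariants(self, phantom_sample):
        three_n, mask_n, rec = preprocess_to_nspace(phantom_sample.image,
                                                    phantom_sample.mask)
        assert three_n.shape[0] == three_n.shape[1] == rec.N
        r0, c0, r1, c1 = rec.crop_box
        assert rec.N == max(r1 - r0, c1 - c0)

    def test_mask_roundtrip_dice(self, phantom_batch):
        """preprocess -> restore recovers masses of radius >= 8 px with
        dice >= 0.95 at model size 128."""
        for s in phantom_batch:
            _, mask_m, rec = preprocess(s.image, s.mask, model_size=128)
            restored = binarize(restore_to_original(mask_m.astype(float), rec))
            inter = np.logical_and(restored, s.mask).sum()
            dice = 2 * inter / (restored.sum() + s.mask.sum())
            assert dice >= 0.95


class TestRestoreToOriginal:
    def test_identity_record(self):
        m = np.arange(64.0).reshape(8, 8) / 64
        rec = CropRecord(flipped=False, crop_box=(0, 0, 8, 8), pad=(0, 0),
                         original_size=(8, 8), model_size=8, N=8)
        assert np.allclose(restore_to_original(m, rec), m)

    def test_crop_region_ones_elsewhere_zero(self):
        rec = CropRecord(flipped=False, crop_box=(2, 0, 10, 8), pad=(0, 0),
                         original_size=(16, 16), model_size=8, N=8)
        out = restore_to_original(np.ones((8, 8)), rec)
        assert np.all(out[2:10, 0:8] == 1)
        assert out.sum() == 64

    def test_shape_mismatch_raises(self):
        rec = CropRecord(flipped=False, crop_box=(0, 0, 8, 8), pad=(0, 0),
                         original_size=(8, 8), model_size=8, N=8)
        with pytest.raises(ValueError):
            restore_to_original(np.ones((9, 9)), rec)

    def test_record_json_roundtrip(self):
        rec = CropRecord(flipped=True, crop_box=(1, 2, 30, 40), pad=(10, 0),
                         original_size=(64, 64), model_size=32, N=38)
        assert CropRecord.from_json(rec.to_json()) == rec


class TestReadImage:
    def test_png_scaled_to_unit_interval(self, tmp_path, rng):
        import imageio.v3 as iio

        from mammoseg.preprocess import read_image

        arr = (rng.uniform(0, 1, (16, 16)) * 255).astype(np.uint8)
        iio.imwrite(tmp_path / "x.png", arr)
        out = read_image(tmp_path / "x.png")
        assert np.allclose(out, arr / 255.0)

    def test_dicom_rescale_applied(self, tmp_path):
        from pydicom.dataset import Dataset, FileMetaDataset
        from pydicom.uid import ExplicitVRLittleEndian, generate_uid

        from mammoseg.preprocess import read_image

        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = generate_uid()
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = Dataset()
        ds.file_meta = meta
        arr = np.arange(64, dtype=np.uint16).reshape(8, 8) * 100
        ds.Rows, ds.Columns = 8, 8
        ds.BitsAllocated, ds.BitsStored, ds.HighBit = 16, 16, 15
        ds.PixelRepresentation = 0
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.RescaleSlope, ds.RescaleIntercept = 2.0, -10.0
        ds.PixelData = arr.tobytes()
        path = tmp_path / "x.dcm"
        ds.save_as(path, enforce_file_format=True)
        out = read_image(path)
        rescaled = arr * 2.0 - 10.0
        expected = (rescaled - rescaled.min()) / np.ptp(rescaled)
        assert np.allclose(out, expected)


class TestAugmentPair:
    def test_identity_params_unchanged(self, phantom_sample):
        img, msk = augment_pair(phantom_sample.image, phantom_sample.mask,
                                params={})
        assert np.allclose(img, phantom_sample.image)
        assert np.array_equal(msk, phantom_sample.mask)

    def test_translation_moves_marker_exactly(self):
        img = np.zeros((100, 100))
        img[50, 50] = 1.0
        msk = (img > 0).astype(np.uint8)
        out, m = augment_pair(img, msk, params={"translate_frac": (0.2, 0.0)})
        assert out[70, 50] > 0.5
        assert m[70, 50] == 1 and m.sum() == 1

    def test_rotation_preserves_component_count(self, phantom_sample):
        _, m = augment_pair(phantom_sample.image, phantom_sample.mask,
                            params={"rotation_deg": 15})
        n_orig = ndimage.label(phantom_sample.mask)[1]
        assert ndimage.label(m)[1] == n_orig

    def test_out_of_range_params_rejected(self, phantom_sample):
        with pytest.raises(ValueError):
            augment_pair(phantom_sample.image, phantom_sample.mask,
                         params={"rotation_deg": 45})
        with pytest.raises(ValueError):
            augment_pair(phantom_sample.image, phantom_sample.mask,
                         params={"translate_frac": (0.5, 0)})

    def test_seeded_draw_is_deterministic(self, phantom_sample):
        a = augment_pair(phantom_sample.image, phantom_sample.mask, seed=5)
        b = augment_pair(phantom_sample.image, phantom_sample.mask, seed=5)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])
        assert set(np.unique(a[1])) <= {0, 1}
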