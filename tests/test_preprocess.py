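"""Frame loading, Otsu thresholding, periphery removal and resizing."""

import numpy as np
import pytest
from PIL import Image

from rectuseg.core import (
    BinaryMask,
    CalibrationError,
    DegenerateInputError,
    Frame,
)
from rectuseg.phantom import generate_phantom, generate_raw_frame
from rectuseg.preprocess import (
    load_frame,
    otsu_threshold,
    resize_mask_to_model,
    resize_to_model,
    strip_periphery,
)

from conftest import tiny_spec


def brute_force_otsu(pixels: np.ndarray) -> int:
    """Independent oracle: exhaustive search over all 256 candidate levels,
    maximizing between-class variance, ties toward the lower level."""
    hist = np.bincount(pixels.ravel().astype(np.uint8), minlength=256)
    total = hist.sum()
    best_t, best_v = None, -1.0
    levels = np.arange(256)
    for t in range(255):
        w0 = hist[: t + 1].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (hist[: t + 1] * levels[: t + 1]).sum() / w0
        mu1 = (hist[t + 1 :] * levels[t + 1 :]).sum() / w1
        v = w0 * w1 * (mu0 - mu1) ** 2
        if v > best_v:
            best_v, best_t = v, t
    return best_t


class TestOtsu:
    def test_two_level_image(self):
        img = np.zeros((10, 10), dtype=np.uint8)
        img[5:] = 255
        t = otsu_threshold(img)
        assert t == brute_force_otsu(img)
        assert 0 <= t < 255

    def test_matches_exhaustive_oracle_on_random_images(self, rng):
        for _ in range(100):
            img = rng.integers(0, 256, size=(20, 20), dtype=np.uint8)
            assert otsu_threshold(img) == brute_force_otsu(img)

    def test_bimodal_threshold_between_modes(self, rng):
        a = np.clip(rng.normal(50, 8, 600), 0, 255)
        b = np.clip(rng.normal(200, 8, 600), 0, 255)
        img = np.concatenate([a, b]).round().astype(np.uint8).reshape(40, 30)
        t = otsu_threshold(img)
        assert 50 < t < 200
        assert t == brute_force_otsu(img)

    def test_constant_image_rejected(self):
        with pytest.raises(DegenerateInputError):
            otsu_threshold(np.full((5, 5), 7, dtype=np.uint8))


class TestLoadFrame:
    def test_png_passthrough_with_arg_calibration(self, tmp_path, rng):
        arr = rng.integers(0, 256, size=(12, 16), dtype=np.uint8)
        p = tmp_path / "f.png"
        Image.fromarray(arr, mode="L").save(p)
        f = load_frame(p, pixel_size_mm=0.2)
        assert f.pixel_size_mm == (0.2, 0.2)
        assert np.array_equal(f.pixels, arr)

    def test_rgb_png_of_gray_image_gives_same_grid(self, tmp_path, rng):
        arr = rng.integers(0, 256, size=(12, 16), dtype=np.uint8)
        rgb = np.stack([arr, arr, arr], axis=-1)
        p = tmp_path / "rgb.png"
        Image.fromarray(rgb, mode="RGB").save(p)
        f = load_frame(p, pixel_size_mm=0.3)
        assert np.array_equal(f.pixels, arr)

    def test_png_without_calibration_rejected(self, tmp_path):
        p = tmp_path / "f.png"
        Image.fromarray(np.zeros((4, 4), np.uint8), mode="L").save(p)
        with pytest.raises(CalibrationError):
            load_frame(p)

    def test_dicom_pixel_spacing_wins(self, tmp_path, rng):
        pydicom = pytest.importorskip("pydicom")
        from pydicom.dataset import FileDataset, FileMetaDataset
        from pydicom.uid import ExplicitVRLittleEndian, generate_uid

        arr = rng.integers(0, 256, size=(8, 10), dtype=np.uint8)
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = generate_uid()
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = FileDataset(str(tmp_path / "f.dcm"), {}, file_meta=meta, preamble=b"\0" * 128)
        ds.Rows, ds.Columns = arr.shape
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 8
        ds.BitsStored = 8
        ds.HighBit = 7
        ds.PixelRepresentation = 0
        ds.PixelSpacing = ["0.1", "0.15"]
        ds.PixelData = arr.tobytes()
        path = tmp_path / "f.dcm"
        ds.save_as(path, enforce_file_format=True)

        f = load_frame(path, pixel_size_mm=0.2)  # embedded calibration wins
        assert f.pixel_size_mm == (0.1, 0.15)
        assert np.array_equal(f.pixels, arr)

    def test_missing_file(self, tmp_path):
        with pytest.raises(IOError):
            load_frame(tmp_path / "nope.png", pixel_size_mm=0.2)


class TestStripPeriphery:
    def test_recovers_phantom_crop_box(self):
        for seed in range(5):
            sample = generate_phantom(tiny_spec(seed=seed))
            raw = generate_raw_frame(sample, margin_px=24, seed=seed + 100)
            crop = strip_periphery(raw.image)
            assert crop.box == raw.crop_box

    def test_full_bright_frame_is_identity(self, rng):
        arr = rng.integers(100, 256, size=(20, 30), dtype=np.uint8)
        arr[0, 0] = 0  # ensure two intensity classes exist
        f = Frame(arr, (0.2, 0.2))
        crop = strip_periphery(f)
        assert crop.box == (0, 19, 0, 29)

    def test_largest_component_selected(self):
        arr = np.zeros((60, 60), dtype=np.uint8)
        arr[5:45, 5:30] = 200  # 40x25 = 1000 px
        arr[50:55, 45:55] = 200  # 50 px
        f = Frame(arr, (0.2, 0.2))
        crop = strip_periphery(f)
        assert crop.box == (5, 44, 5, 29)

    def test_idempotent_on_own_output(self):
        sample = generate_phantom(tiny_spec(seed=8))
        raw = generate_raw_frame(sample, margin_px=24, seed=9)
        first = strip_periphery(raw.image)
        second = strip_periphery(first.cropped)
        h, w = first.cropped.shape
        assert second.box == (0, h - 1, 0, w - 1)


class TestResize:
    def test_identity_when_already_target(self, rng):
        arr = rng.integers(0, 256, size=(64, 64), dtype=np.uint8)
        f = Frame(arr, (0.2, 0.2))
        out = resize_to_model(f, target=64)
        assert np.array_equal(out.pixels, arr)
        assert out.pixel_size_mm == (0.2, 0.2)

    def test_anisotropic_pixel_size_update(self, rng):
        arr = rng.integers(0, 256, size=(128, 64), dtype=np.uint8)
        f = Frame(arr, (0.1, 0.1))
        out = resize_to_model(f, target=64)
        assert out.pixel_size_mm == pytest.approx((0.2, 0.1))

    def test_constant_image_stays_constant(self):
        f = Frame(np.full((40, 60), 137, dtype=np.uint8), (0.3, 0.3))
        out = resize_to_model(f, target=32)
        assert (out.pixels == 137).all()

    def test_physical_extent_conserved(self, rng):
        for _ in range(10):
            h = int(rng.integers(30, 200))
            w = int(rng.integers(30, 200))
            ps = float(rng.uniform(0.05, 0.5))
            f = Frame(rng.integers(0, 256, size=(h, w), dtype=np.uint8), (ps, ps))
            out = resize_to_model(f, target=64)
            for axis in (0, 1):
                before = f.shape[axis] * f.pixel_size_mm[axis]
                after = 64 * out.pixel_size_mm[axis]
                assert abs(before - after) < max(f.pixel_size_mm)  # within 1 px-worth

    def test_mask_resize_stays_binary(self, rng):
        m = BinaryMask((rng.random((100, 70)) < 0.4).astype(np.uint8), (0.2, 0.2))
        out = resize_mask_to_model(m, target=64)
        assert set(np.unique(out.values)) <= {0, 1}
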