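"""Patient-level splitting, augmentation, loss and the fit protocol."""

import numpy as np
import pytest

import rectuseg.train as train_mod
from rectuseg.core import ParameterError
from rectuseg.nets import NetConfig, build_model
from rectuseg.phantom import generate_dataset
from rectuseg.train import TrainConfig, augment, bce_loss, fit, split_patients

from conftest import tiny_spec


def _ids(n):
    return [f"P{i:03d}" for i in range(n)]


class TestSplitPatients:
    def test_exact_proportions_for_ten_patients(self):
        split = split_patients(_ids(10), ratio=(7, 1, 2), seed=0)
        sizes = {s: len(split.patients(s)) for s in ("train", "val", "test")}
        assert sizes == {"train": 7, "val": 1, "test": 2}

    def test_largest_remainder_for_ninety_four(self):
        split = split_patients(_ids(94), ratio=(7, 1, 2), seed=1)
        sizes = [len(split.patients(s)) for s in ("train", "val", "test")]
        assert sum(sizes) == 94
        for got, exact in zip(sizes, (65.8, 9.4, 18.8)):
            assert abs(got - exact) <= 1

    def test_partition_disjoint_and_exhaustive(self):
        ids = _ids(23)
        for seed in range(10):
            split = split_patients(ids, seed=seed)
            subsets = [set(split.patients(s)) for s in ("train", "val", "test")]
            assert set().union(*subsets) == set(ids)
            assert sum(len(s) for s in subsets) == len(ids)

    def test_all_subsets_nonempty_with_three_patients(self):
        split = split_patients(_ids(3), ratio=(7, 1, 2), seed=5)
        assert all(len(split.patients(s)) == 1 for s in ("train", "val", "test"))

    def test_too_few_patients_rejected(self):
        with pytest.raises(ParameterError):
            split_patients(_ids(2))

    def test_seeded_permutation(self):
        a = split_patients(_ids(12), seed=3)
        b = split_patients(_ids(12), seed=3)
        c = split_patients(_ids(12), seed=4)
        assert a.assignment == b.assignment
        assert a.assignment != c.assignment


class TestAugment:
    def _cfg(self, flip_prob, gain):
        eps = 1e-9
        return TrainConfig(flip_prob=flip_prob, contrast_range=(gain - eps, gain + eps))

    def test_identity_when_disabled(self, rng):
        img = rng.integers(0, 256, size=(16, 16), dtype=np.uint8)
        mask = (rng.random((16, 16)) > 0.5).astype(np.uint8)
        out_img, out_mask = augment(img, mask, self._cfg(0.0, 1.0), rng=1)
        assert np.array_equal(out_img, img)
        assert np.array_equal(out_mask, mask)

    def test_flip_is_involution(self, rng):
        img = rng.integers(0, 256, size=(16, 16), dtype=np.uint8)
        mask = (rng.random((16, 16)) > 0.5).astype(np.uint8)
        cfg = self._cfg(1.0, 1.0)
        once_img, once_mask = augment(img, mask, cfg, rng=1)
        twice_img, twice_mask = augment(once_img, once_mask, cfg, rng=2)
        assert np.array_equal(twice_img, img)
        assert np.array_equal(twice_mask, mask)
        assert not np.array_equal(once_img, img)

    def test_contrast_pivot_at_mid_gray(self):
        img = np.full((8, 8), 128, dtype=np.uint8)
        mask = np.zeros((8, 8), dtype=np.uint8)
        out_img, _ = augment(img, mask, self._cfg(0.0, 1.3), rng=1)
        assert np.array_equal(out_img, img)  # gain pivots around 128

    def test_mask_never_intensity_transformed(self, rng):
        img = rng.integers(0, 256, size=(8, 8), dtype=np.uint8)
        mask = (rng.random((8, 8)) > 0.5).astype(np.uint8)
        _, out_mask = augment(img, mask, TrainConfig(), rng=3)
        assert set(np.unique(out_mask)) <= {0, 1}


class TestBceLoss:
    def test_perfect_prediction_near_zero(self, rng):
        y = (rng.random((10, 10)) > 0.5).astype(np.uint8)
        assert bce_loss(y.astype(np.float64), y) < 1e-5

    def test_uniform_half_is_ln_two(self):
        y = np.zeros((6, 6), dtype=np.uint8)
        y[:3] = 1
        assert bce_loss(np.full((6, 6), 0.5), y) == pytest.approx(np.log(2), abs=1e-9)

    def test_hand_computed_two_by_two(self):
        pred = np.array([[0.9, 0.2], [0.8, 0.6]])
        gt = np.array([[1, 0], [1, 1]], dtype=np.uint8)
        expected = np.mean([-np.log(0.9), -np.log(0.8), -np.log(0.8), -np.log(0.6)])
        assert bce_loss(pred, gt) == pytest.approx(expected, rel=1e-12)

    def test_shape_mismatch(self):
        from rectuseg.core import ShapeError

        with pytest.raises(ShapeError):
            bce_loss(np.zeros((2, 2)), np.zeros((3, 3), dtype=np.uint8))


def _tiny_dataset(n_patients=6, seed=0):
    base = tiny_spec(height_px=32, width_px=32, pixel_size_mm=1.0,
                     muscle_width_mm=9.0, muscle_thickness_mm=6.0, gap_mm=5.0)
    return generate_dataset(n_patients, images_per_patient=(2, 3), seed=seed,
                            base_spec=base)


def _tiny_model(seed=0):
    return build_model(NetConfig(variant="plain", depth=2, base_channels=4, seed=seed))


class TestFit:
    def test_history_bookkeeping(self):
        ds = _tiny_dataset()
        split = split_patients([p for p, _ in ds], seed=0)
        cfg = TrainConfig(max_epochs=3, early_stop_patience=15, seed=0)
        best, history = fit(_tiny_model(), ds, split, cfg)
        assert len(history) <= 3
        assert {"epoch", "train_loss", "val_dice", "val_iou"} <= set(history[0])
        assert 0 <= best["epoch"] < len(history)

    def test_best_checkpoint_dominates_history(self):
        ds = _tiny_dataset(seed=2)
        split = split_patients([p for p, _ in ds], seed=2)
        cfg = TrainConfig(max_epochs=4, early_stop_patience=15, seed=2)
        best, history = fit(_tiny_model(seed=2), ds, split, cfg)
        assert best["val_dice"] >= max(h["val_dice"] for h in history)

    def test_early_stop_with_constant_validation_metric(self, monkeypatch):
        monkeypatch.setattr(
            train_mod, "_validation_scores", lambda *a, **k: (50.0, 40.0)
        )
        ds = _tiny_dataset(seed=3)
        split = split_patients([p for p, _ in ds], seed=3)
        cfg = TrainConfig(max_epochs=10, early_stop_patience=1, seed=3)
        _, history = fit(_tiny_model(seed=3), ds, split, cfg)
        assert len(history) == 2  # epoch 0 sets the best; epoch 1 triggers the stop

    def test_fixed_seed_reproduces_history(self):
        ds = _tiny_dataset(seed=4)
        split = split_patients([p for p, _ in ds], seed=4)
        cfg = TrainConfig(max_epochs=2, early_stop_patience=15, seed=4)
        _, h1 = fit(_tiny_model(seed=4), ds, split, cfg)
        _, h2 = fit(_tiny_model(seed=4), ds, split, cfg)
        assert h1 == h2

    @pytest.mark.parametrize("variant", ("plain", "nested", "residual"))
    def test_loss_halves_within_ten_epochs(self, variant):
        base = tiny_spec(height_px=64, width_px=64, pixel_size_mm=0.8,
                         muscle_width_mm=12.0, muscle_thickness_mm=7.0,
                         gap_mm=6.0)
        ds = generate_dataset(24, images_per_patient=(4, 5), seed=5,
                              base_spec=base)
        split = split_patients([p for p, _ in ds], seed=5)
        model = build_model(
            NetConfig(variant=variant, depth=3, base_channels=8, seed=5)
        )
        cfg = TrainConfig(max_epochs=10, early_stop_patience=15, seed=5)
        _, history = fit(model, ds, split, cfg)
        assert history[-1]["train_loss"] <= 0.5 * history[0]["train_loss"]
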