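"""Architecture contracts: shapes, seeding, parameter counts, gradients."""

import numpy as np
import pytest

from rectuseg.core import Frame, ParameterError, ShapeError
from rectuseg.nets import (
    NetConfig,
    _sigmoid,
    build_model,
    count_parameters,
    load_checkpoint,
    predict,
    predict_batch,
    save_checkpoint,
)
from rectuseg.train import bce_loss

VARIANTS = ("plain", "nested", "residual")


def tiny_config(variant, depth=3, base=8, seed=1):
    return NetConfig(variant=variant, depth=depth, base_channels=base, seed=seed)


class TestBuildModel:
    @pytest.mark.parametrize("variant", VARIANTS)
    def test_output_shape_and_probability_range(self, variant, rng):
        model = build_model(tiny_config(variant))
        x = rng.random((1, 64, 64, 1), dtype=np.float32)
        p = predict_batch(model, x)
        assert p.shape == (1, 64, 64)
        assert np.isfinite(p).all()
        assert p.min() >= 0.0 and p.max() <= 1.0

    @pytest.mark.parametrize("variant", VARIANTS)
    def test_same_seed_same_parameters(self, variant):
        a = build_model(tiny_config(variant, seed=7))
        b = build_model(tiny_config(variant, seed=7))
        assert all(
            np.array_equal(x, y) for x, y in zip(a.state_arrays(), b.state_arrays())
        )
        c = build_model(tiny_config(variant, seed=8))
        assert any(
            not np.array_equal(x, y)
            for x, y in zip(a.state_arrays(), c.state_arrays())
        )

    def test_plain_parameter_count_analytic(self):
        # depth 3, base 8 (channels 8/16/32), double-conv blocks with BN:
        # enc: 680 + 3520 + 13952; up-convs: 4640 + 1168;
        # dec: 6976 + 1760; 1x1 head: 9  -> 32705
        model = build_model(tiny_config("plain"))
        assert count_parameters(model) == 32705

    def test_residual_larger_than_plain(self):
        plain = count_parameters(build_model(tiny_config("plain")))
        residual = count_parameters(build_model(tiny_config("residual")))
        nested = count_parameters(build_model(tiny_config("nested")))
        assert residual > plain  # projection shortcuts add parameters
        assert nested > plain  # dense intermediate skip nodes add parameters

    def test_invalid_config_rejected(self):
        with pytest.raises(ParameterError):
            NetConfig(variant="attention")
        with pytest.raises(ParameterError):
            NetConfig(depth=1)

    def test_indivisible_grid_rejected(self, rng):
        model = build_model(tiny_config("plain", depth=3))
        with pytest.raises(ShapeError):
            model.forward(rng.random((1, 66, 66, 1), dtype=np.float32))


class TestPredict:
    def test_deterministic_and_finite(self, rng):
        model = build_model(tiny_config("residual"))
        frame = Frame(
            rng.integers(0, 256, size=(64, 64), dtype=np.uint8), (0.3, 0.3)
        )
        p1 = predict(model, frame)
        p2 = predict(model, frame)
        assert np.isfinite(p1.values).all()
        assert np.array_equal(p1.values, p2.values)  # inference is bitwise stable
        assert p1.pixel_size_mm == frame.pixel_size_mm

    def test_checkpoint_roundtrip(self, tmp_path, rng):
        model = build_model(tiny_config("nested", depth=2, base=4))
        x = rng.random((1, 32, 32, 1), dtype=np.float32)
        before = predict_batch(model, x)
        path = tmp_path / "ckpt.npz"
        save_checkpoint(model, path)
        restored = load_checkpoint(path)
        assert restored.config.variant == "nested"
        assert np.array_equal(predict_batch(restored, x), before)


class TestGradients:
    @pytest.mark.parametrize("variant", VARIANTS)
    def test_backward_matches_finite_differences(self, variant):
        rng = np.random.default_rng(0)
        model = build_model(tiny_config(variant, depth=2, base=2, seed=3))
        x = rng.random((2, 8, 8, 1)).astype(np.float32)
        y = (rng.random((2, 8, 8)) > 0.5).astype(np.float32)

        def loss():
            p = _sigmoid(model.forward(x, train=True))
            return bce_loss(p, y), p

        _, p = loss()
        model.zero_grad()
        model.backward((p - y) / p.size)
        params = model.parameters()
        for pi in rng.choice(len(params), size=5, replace=False):
            par = params[pi]
            idx = tuple(rng.integers(0, s) for s in par.value.shape)
            analytic = par.grad[idx]
            h = 1e-3
            old = par.value[idx]
            par.value[idx] = old + h
            lp, _ = loss()
            par.value[idx] = old - h
            lm, _ = loss()
            par.value[idx] = old
            numeric = (lp - lm) / (2 * h)
            assert analytic == pytest.approx(numeric, abs=5e-4, rel=5e-2)


class TestLearning:
    @pytest.mark.parametrize("variant", VARIANTS)
    def test_one_epoch_decreases_training_loss(self, variant):
        from rectuseg.phantom import generate_phantom
        from rectuseg.train import Adam

        from conftest import tiny_spec

        samples = [generate_phantom(tiny_spec(seed=s, height_px=32, width_px=32,
                                              pixel_size_mm=1.0, gap_mm=4.0,
                                              muscle_width_mm=9.0,
                                              muscle_thickness_mm=6.0))
                   for s in range(8)]
        x = np.stack([s.image.pixels for s in samples]).astype(np.float32) / 255.0
        x = x[..., None]
        y = np.stack([s.mask.values for s in samples]).astype(np.float32)
        model = build_model(tiny_config(variant, depth=2, base=4, seed=2))
        opt = Adam(model.parameters(), lr=0.001, beta1=0.9)
        losses = []
        for _ in range(4):  # one epoch of batch-8 steps, repeated on the batch
            p = _sigmoid(model.forward(x, train=True))
            losses.append(bce_loss(p, y))
            model.zero_grad()
            model.backward((p - y) / p.size)
            opt.step()
        p = _sigmoid(model.forward(x, train=True))
        losses.append(bce_loss(p, y))
        assert losses[-1] < losses[0]

    def test_flip_augmented_model_is_approximately_flip_equivariant(self):
        """A model trained with horizontal-flip augmentation on left/right
        symmetric phantoms maps a mirrored frame to (approximately) the
        mirrored probability map."""
        from rectuseg.core import Frame
        from rectuseg.phantom import PhantomSpec, generate_dataset
        from rectuseg.train import TrainConfig, fit, split_patients

        base = PhantomSpec(height_px=64, width_px=64, pixel_size_mm=0.8,
                           gap_mm=6.0, muscle_width_mm=12.0,
                           muscle_thickness_mm=7.0)
        ds = generate_dataset(16, images_per_patient=(3, 4), seed=9,
                              base_spec=base)
        split = split_patients([p for p, _ in ds], seed=9)
        model = build_model(
            NetConfig(variant="plain", depth=3, base_channels=8, seed=9)
        )
        fit(model, ds, split,
            TrainConfig(max_epochs=8, early_stop_patience=15, seed=9,
                        flip_prob=0.5))
        for _, sample in ds[:5]:
            f = sample.image
            flipped = Frame(f.pixels[:, ::-1].copy(), f.pixel_size_mm)
            p_of_flip = predict(model, flipped).values
            flip_of_p = predict(model, f).values[:, ::-1]
            assert np.abs(p_of_flip - flip_of_p).mean() < 0.15
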