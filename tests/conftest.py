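"""Shared fixtures: small phantoms and tiny network/training configs."""

import numpy as np
import pytest

from rectuseg.core import BinaryMask
from rectuseg.phantom import PhantomSpec, generate_phantom


def tiny_spec(**overrides) -> PhantomSpec:
    """A 64x64 phantom at 0.5 mm/px — small enough for fast unit tests."""
    kwargs = dict(
        height_px=64,
        width_px=64,
        pixel_size_mm=0.5,
        gap_mm=4.0,
        muscle_width_mm=9.0,
        muscle_thickness_mm=6.0,
        n_distractors=1,
        seed=0,
    )
    kwargs.update(overrides)
    return PhantomSpec(**kwargs)


@pytest.fixture
def tiny_sample():
    return generate_phantom(tiny_spec(seed=3))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_mask(rng: np.random.Generator, shape=(24, 24), p=0.3,
                pixel_size=(1.0, 1.0)) -> BinaryMask:
    return BinaryMask((rng.random(shape) < p).astype(np.uint8), pixel_size)
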