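"""Seeded synthetic abdominal-ultrasound phantoms with known ground truth.

Clinical rectus-abdominis ultrasound data is not publicly available, so the
pipeline is exercised on phantoms that emulate the salient image content of a
transverse abdominal B-mode frame:

* speckle texture — the magnitude of a low-pass-filtered complex Gaussian
  field, scaled by a per-tissue-class mean (Rayleigh-like, the simplest
  ultrasound-looking texture model);
* two hypoechoic (dark) quasi-elliptical muscle bodies separated laterally by
  a configurable gap across the linea alba, with their inner/outer fascia
  rendered as a bright outline;
* optional raw-frame mode: the scan region embedded in a black periphery
  scattered with small bright text-like annotation clusters, as exported by
  an ultrasound machine.

The construction guarantees that every column of each muscle's lateral span
contains at least one mask pixel and that the corridor between the two bodies
is empty, so the recorded ``true_gap_px`` equals exactly the number of
background columns strictly between the two components — the quantity the
measurement stage recovers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.ndimage import binary_dilation, gaussian_filter, gaussian_filter1d
from skimage.morphology import disk

from .core import BinaryMask, Frame, ParameterError
from .preprocess import save_frame_png
from .postprocess import save_mask_png

__all__ = [
    "PhantomSpec",
    "PhantomSample",
    "generate_phantom",
    "generate_raw_frame",
    "generate_dataset",
    "default_gap_sampler",
    "write_dataset",
]

# per-tissue-class mean intensities (8-bit); muscle is hypoechoic, fascia
# hyperechoic, so the ordering fascia > background tissue > muscle is built in
_MEAN_MUSCLE = 70.0
_MEAN_TISSUE = 115.0
_MEAN_FASCIA = 205.0
_INTENSITY_FLOOR = 25  # keeps the scan region separable from a black periphery


@dataclass
class PhantomSpec:
    """Geometry, calibration and randomness of one phantom frame."""

    height_px: int = 256
    width_px: int = 256
    pixel_size_mm: float = 0.3
    gap_mm: float = 10.0
    muscle_width_mm: float = 18.0
    muscle_thickness_mm: float = 9.0
    n_distractors: int = 3
    raw_mode: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height_px <= 0 or self.width_px <= 0:
            raise ParameterError("phantom dimensions must be positive")
        if self.pixel_size_mm <= 0:
            raise ParameterError("pixel_size_mm must be positive")
        if self.gap_mm < 0:
            raise ParameterError("gap_mm must be non-negative")
        if self.muscle_width_mm <= 0 or self.muscle_thickness_mm <= 0:
            raise ParameterError("muscle dimensions must be positive")
        if self.n_distractors < 0:
            raise ParameterError("n_distractors must be non-negative")
        lateral_extent = self.width_px * self.pixel_size_mm
        if self.gap_mm + 2 * self.muscle_width_mm >= lateral_extent:
            raise ParameterError(
                "gap plus both muscles must fit laterally: "
                f"{self.gap_mm} + 2*{self.muscle_width_mm} >= {lateral_extent}"
            )


@dataclass
class PhantomSample:
    """A generated frame, its ground-truth mask and the true separation."""

    image: Frame
    mask: BinaryMask
    true_gap_px: int
    true_gap_mm: float
    crop_box: Optional[Tuple[int, int, int, int]] = None  # raw-mode only
    text_boxes: List[Tuple[int, int, int, int]] = field(default_factory=list)


def _smooth_noise(rng: np.random.Generator, n: int, sigma: float) -> np.ndarray:
    return gaussian_filter1d(rng.normal(0.0, 1.0, size=n), sigma=sigma, mode="nearest")


def _paint_muscle(
    mask: np.ndarray,
    rng: np.random.Generator,
    c0: int,
    c1: int,
    center_row: int,
    half_thickness_px: float,
) -> None:
    """Fill a lens-shaped body spanning columns c0..c1 (inclusive), with a
    smoothly perturbed vertical half-thickness.  Every column of the span gets
    at least one pixel and all column runs contain ``center_row``, which keeps
    the body connected and its lateral extent exact."""
    h = mask.shape[0]
    ncols = c1 - c0 + 1
    wobble = 0.15 * _smooth_noise(rng, ncols, sigma=max(2.0, ncols / 8.0))
    half_span = (ncols - 1) / 2.0 if ncols > 1 else 1.0
    for k in range(ncols):
        u = (k - half_span) / half_span if ncols > 1 else 0.0
        base = half_thickness_px * np.sqrt(max(0.0, 1.0 - u * u))
        ht = max(1, int(round(base * (1.0 + wobble[k]))))
        r0 = max(0, center_row - ht)
        r1 = min(h - 1, center_row + ht)
        mask[r0 : r1 + 1, c0 + k] = 1


def _render_image(
    rng: np.random.Generator, mask: np.ndarray, n_distractors: int
) -> np.ndarray:
    h, w = mask.shape
    fascia = binary_dilation(mask.astype(bool), structure=disk(2)) & ~mask.astype(bool)
    mean_map = np.full((h, w), _MEAN_TISSUE, dtype=np.float64)
    mean_map[fascia] = _MEAN_FASCIA
    mean_map[mask.astype(bool)] = _MEAN_MUSCLE
    # small bright/dark blobs in the surrounding tissue (vessels, fat lobules)
    body = mask.astype(bool) | fascia
    for _ in range(n_distractors):
        for _attempt in range(50):
            r = int(rng.integers(4, h - 4))
            c = int(rng.integers(4, w - 4))
            if not body[r, c]:
                break
        rad = int(rng.integers(2, 5))
        level = float(rng.choice([45.0, 230.0]))
        rr, cc = np.ogrid[:h, :w]
        blob = ((rr - r) ** 2 + (cc - c) ** 2 <= rad * rad) & ~body
        mean_map[blob] = level
    # Rayleigh-like speckle: magnitude of a low-pass-filtered complex field
    z_re = gaussian_filter(rng.normal(0.0, 1.0, size=(h, w)), sigma=1.2)
    z_im = gaussian_filter(rng.normal(0.0, 1.0, size=(h, w)), sigma=1.2)
    speckle = np.hypot(z_re, z_im)
    speckle /= speckle.mean()
    img = np.clip(mean_map * speckle, _INTENSITY_FLOOR, 255.0)
    return np.round(img).astype(np.uint8)


def generate_phantom(spec: PhantomSpec) -> PhantomSample:
    """Generate one phantom frame with its ground-truth mask.

    Deterministic for a fixed seed.  ``true_gap_px`` equals the count of
    background columns strictly between the two muscle components (0 when
    ``gap_mm`` is 0, in which case the two bodies merge into one region).
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height_px, spec.width_px
    px = spec.pixel_size_mm

    gap_px = 0 if spec.gap_mm == 0 else max(1, int(round(spec.gap_mm / px)))
    mw_px = max(3, int(round(spec.muscle_width_mm / px)))
    half_t = max(1.5, spec.muscle_thickness_mm / px / 2.0)

    c_mid = w // 2
    if gap_px > 0:
        left_c1 = c_mid - gap_px // 2 - 1
        right_c0 = left_c1 + gap_px + 1
    else:
        left_c1 = c_mid - 1
        right_c0 = c_mid  # adjacent columns -> a single merged region
    left_c0 = left_c1 - mw_px + 1
    right_c1 = right_c0 + mw_px - 1
    if left_c0 < 0 or right_c1 > w - 1:
        raise ParameterError("muscles do not fit laterally at this pixel size")

    mask = np.zeros((h, w), dtype=np.uint8)
    jitter = max(1, h // 20)
    row_l = h // 2 + int(rng.integers(-jitter, jitter + 1))
    row_r = h // 2 + int(rng.integers(-jitter, jitter + 1))
    if gap_px == 0:
        # merged muscles must touch: adjacent columns only connect when the
        # two bodies share their center row
        row_r = row_l
    _paint_muscle(mask, rng, left_c0, left_c1, row_l, half_t)
    _paint_muscle(mask, rng, right_c0, right_c1, row_r, half_t)

    img = _render_image(rng, mask, spec.n_distractors)
    frame = Frame(img, (px, px), source_id=f"phantom-s{spec.seed}")
    sample = PhantomSample(
        image=frame,
        mask=BinaryMask(mask, (px, px)),
        true_gap_px=gap_px,
        true_gap_mm=gap_px * px,
    )
    if spec.raw_mode:
        margin = max(16, h // 8)
        sample = generate_raw_frame(sample, margin_px=margin, seed=spec.seed + 1)
    return sample


def generate_raw_frame(
    sample: PhantomSample, margin_px: int, seed: int
) -> PhantomSample:
    """Embed a phantom in a black periphery with text-like clusters.

    The scan region is pasted at offset ``margin_px`` into a black canvas;
    small bright pixel clusters (device/acquisition annotations) are scattered
    in the periphery, at least 2 px away from the scan region.  ``crop_box``
    records the embedded rectangle (inclusive bounds) and the mask is shifted
    consistently.
    """
    if margin_px < 0:
        raise ParameterError("margin_px must be non-negative")
    rng = np.random.default_rng(seed)
    h, w = sample.image.shape
    m = margin_px
    canvas = np.zeros((h + 2 * m, w + 2 * m), dtype=np.uint8)
    canvas[m : m + h, m : m + w] = sample.image.pixels
    big_mask = np.zeros_like(canvas)
    big_mask[m : m + h, m : m + w] = sample.mask.values
    crop_box = (m, m + h - 1, m, m + w - 1)

    text_boxes: List[Tuple[int, int, int, int]] = []
    if m >= 10:
        ch, cw = 5, min(24, m + w // 4)  # glyph-cluster extent
        bands = [  # (row range, col range) rectangles of the periphery
            (0, m - 3 - ch, 0, canvas.shape[1] - 1 - cw),  # top
            (m + h + 2, canvas.shape[0] - 1 - ch, 0, canvas.shape[1] - 1 - cw),  # bottom
            (0, canvas.shape[0] - 1 - ch, 0, m - 3 - cw),  # left
            (0, canvas.shape[0] - 1 - ch, m + w + 2, canvas.shape[1] - 1 - cw),  # right
        ]
        n_clusters = int(rng.integers(2, 6))
        for _ in range(n_clusters):
            usable = [b for b in bands if b[1] >= b[0] and b[3] >= b[2]]
            if not usable:
                break
            r0_lo, r0_hi, c0_lo, c0_hi = usable[int(rng.integers(len(usable)))]
            r0 = int(rng.integers(r0_lo, r0_hi + 1))
            c0 = int(rng.integers(c0_lo, c0_hi + 1))
            box = (r0, r0 + ch - 1, c0, c0 + cw - 1)
            # reject anything overlapping the (2 px-expanded) scan region
            if not (box[1] < m - 2 or box[0] > m + h + 1 or
                    box[3] < m - 2 or box[2] > m + w + 1):
                continue
            for _g in range(int(rng.integers(8, 20))):  # text-like pixel pairs
                gr = r0 + int(rng.integers(0, ch))
                gc = c0 + int(rng.integers(0, cw - 1))
                level = int(rng.integers(190, 256))
                canvas[gr, gc : gc + 2] = level
            text_boxes.append(box)

    frame = Frame(
        canvas, sample.image.pixel_size_mm, source_id=sample.image.source_id + "-raw"
    )
    return PhantomSample(
        image=frame,
        mask=BinaryMask(big_mask, sample.mask.pixel_size_mm),
        true_gap_px=sample.true_gap_px,
        true_gap_mm=sample.true_gap_mm,
        crop_box=crop_box,
        text_boxes=text_boxes,
    )


def default_gap_sampler(
    rng: np.random.Generator, base_spec: PhantomSpec
) -> PhantomSpec:
    """Draw a per-patient latent spec emulating a postpartum DRA cohort.

    About one patient in five shows non-diagnostic separation (< 2.5 cm);
    the rest are separated, with gaps up to the lateral field of view.
    """
    max_gap = base_spec.width_px * base_spec.pixel_size_mm - 2 * base_spec.muscle_width_mm - 3.0
    if rng.random() < 0.22:
        gap = float(rng.uniform(2.0, min(24.0, max_gap)))
    else:
        gap = float(rng.uniform(min(25.0, max_gap * 0.7), max_gap))
    return replace(base_spec, gap_mm=gap)


def generate_dataset(
    n_patients: int,
    images_per_patient: Tuple[int, int] = (4, 11),
    spec_sampler: Optional[Callable[[np.random.Generator, PhantomSpec], PhantomSpec]] = None,
    seed: int = 0,
    base_spec: Optional[PhantomSpec] = None,
    gap_jitter: float = 0.1,
) -> List[Tuple[str, PhantomSample]]:
    """Generate a patient-structured phantom dataset.

    Each patient gets one latent spec (notably a latent gap) from
    ``spec_sampler`` and between ``images_per_patient[0]`` and
    ``images_per_patient[1]`` views whose gaps jitter around the latent value
    by a relative ``gap_jitter`` (repeated views of the same abdomen are
    correlated).  Deterministic per seed.
    """
    if n_patients < 1:
        raise ParameterError("n_patients must be >= 1")
    lo, hi = images_per_patient
    if lo > hi or lo < 1:
        raise ParameterError(f"empty images-per-patient range {images_per_patient!r}")
    base = base_spec if base_spec is not None else PhantomSpec()
    sampler = spec_sampler if spec_sampler is not None else default_gap_sampler
    rng = np.random.default_rng(seed)
    out: List[Tuple[str, PhantomSample]] = []
    for p in range(n_patients):
        pid = f"P{p:03d}"
        patient_spec = sampler(rng, base)
        n_img = int(rng.integers(lo, hi + 1))
        max_gap = (
            patient_spec.width_px * patient_spec.pixel_size_mm
            - 2 * patient_spec.muscle_width_mm - 1.0
        )
        for _ in range(n_img):
            gap = patient_spec.gap_mm * (1.0 + gap_jitter * rng.normal())
            gap = float(np.clip(gap, 0.0, max_gap))
            img_spec = replace(
                patient_spec, gap_mm=gap, seed=int(rng.integers(0, 2**31 - 1))
            )
            out.append((pid, generate_phantom(img_spec)))
    return out


def write_dataset(
    dataset: Sequence[Tuple[str, PhantomSample]], out_dir: Union[str, Path]
) -> pd.DataFrame:
    """Write image/mask PNG pairs plus a CSV manifest; returns the manifest."""
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (pid, sample) in enumerate(dataset):
        stem = f"{pid}_img{i:04d}"
        img_path = out_dir / "images" / f"{stem}.png"
        mask_path = out_dir / "masks" / f"{stem}.png"
        save_frame_png(sample.image, img_path, sidecar=False)
        save_mask_png(sample.mask, mask_path)
        rows.append(
            {
                "patient_id": pid,
                "image": str(img_path),
                "mask": str(mask_path),
                "pixel_size_mm": sample.image.pixel_size_mm[1],
                "true_gap_px": sample.true_gap_px,
                "true_gap_mm": sample.true_gap_mm,
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(out_dir / "manifest.csv", index=False)
    return df
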