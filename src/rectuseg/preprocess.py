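"""Raw-frame preprocessing: loading, periphery removal and resizing.

Clinical B-mode frames exported from an ultrasound machine carry a black
periphery with burned-in device/acquisition text around the bright scan
sector.  Before segmentation the pipeline (i) loads the DICOM/PNG frame with
its mm/pixel calibration, (ii) strips the periphery by Otsu-binarizing the
frame and cropping the minimum enclosing rectangle of the largest connected
foreground component, and (iii) resizes the crop to the fixed model grid
(512x512 by default), tracking the effective per-axis pixel size so that
pixel gaps measured on the model grid convert exactly to mm.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Tuple, Union

import numpy as np
from PIL import Image
from skimage import measure as _skmeasure
from skimage.transform import resize as _skresize

from .core import (
    BinaryMask,
    CalibrationError,
    CropResult,
    DegenerateInputError,
    Frame,
    ParameterError,
)

__all__ = [
    "load_frame",
    "otsu_threshold",
    "strip_periphery",
    "resize_to_model",
    "resize_mask_to_model",
    "save_frame_png",
]


def load_frame(
    path: Union[str, Path],
    pixel_size_mm: Optional[Union[float, Tuple[float, float]]] = None,
) -> Frame:
    """Load a DICOM or PNG frame as an 8-bit single-channel :class:`Frame`.

    Multi-channel images are converted to luminance.  For DICOM input the
    embedded ``PixelSpacing`` calibration, when present, takes precedence over
    the ``pixel_size_mm`` argument; ``MONOCHROME1`` photometric interpretation
    (white-is-zero) is inverted to the conventional white-is-bright scale.

    Raises
    ------
    CalibrationError
        If neither the file nor the argument provides a pixel size.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    arg_ps = _normalize_pixel_size(pixel_size_mm)

    if path.suffix.lower() in (".dcm", ".dicom") or _looks_like_dicom(path):
        import pydicom

        ds = pydicom.dcmread(str(path))
        arr = ds.pixel_array
        if arr.ndim == 3:  # colour DICOM -> luminance
            arr = _to_luminance(arr)
        arr = _rescale_to_uint8(arr)
        if getattr(ds, "PhotometricInterpretation", "") == "MONOCHROME1":
            arr = 255 - arr
        file_ps = getattr(ds, "PixelSpacing", None)
        if file_ps is not None:
            ps = (float(file_ps[0]), float(file_ps[1]))
        elif arg_ps is not None:
            ps = arg_ps
        else:
            raise CalibrationError(
                f"{path.name}: no PixelSpacing in file and no pixel size given"
            )
        return Frame(arr, ps, source_id=path.stem)

    try:
        img = Image.open(path)
    except Exception as exc:  # unreadable / unsupported
        raise IOError(f"cannot read image {path}: {exc}") from exc
    arr = np.asarray(img)
    if arr.ndim == 3:
        arr = _to_luminance(arr)
    arr = _rescale_to_uint8(arr)
    if arg_ps is None:
        raise CalibrationError(f"{path.name}: PNG carries no calibration; pass pixel_size_mm")
    return Frame(arr, arg_ps, source_id=path.stem)


def _normalize_pixel_size(
    ps: Optional[Union[float, Tuple[float, float]]],
) -> Optional[Tuple[float, float]]:
    if ps is None:
        return None
    if np.isscalar(ps):
        return (float(ps), float(ps))  # type: ignore[arg-type]
    return (float(ps[0]), float(ps[1]))  # type: ignore[index]


def _looks_like_dicom(path: Path) -> bool:
    try:
        with open(path, "rb") as fh:
            fh.seek(128)
            return fh.read(4) == b"DICM"
    except OSError:
        return False


def _to_luminance(arr: np.ndarray) -> np.ndarray:
    rgb = arr[..., :3].astype(np.float64)
    return np.round(rgb @ np.array([0.299, 0.587, 0.114])).astype(arr.dtype)


def _rescale_to_uint8(arr: np.ndarray) -> np.ndarray:
    if arr.dtype == np.uint8:
        return arr
    arr = arr.astype(np.float64)
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        return np.zeros(arr.shape, dtype=np.uint8)
    return np.round((arr - lo) / (hi - lo) * 255.0).astype(np.uint8)


def otsu_threshold(pixels: np.ndarray) -> int:
    """8-bit Otsu threshold maximizing between-class variance.

    The returned level ``t`` splits the histogram into background
    ``intensity <= t`` and foreground ``intensity > t``.  Ties in the
    between-class variance are broken toward the **lower** level.

    Raises
    ------
    DegenerateInputError
        If the image has fewer than two distinct intensity values.
    """
    pixels = np.asarray(pixels)
    if pixels.dtype != np.uint8:
        pixels = np.clip(np.round(pixels), 0, 255).astype(np.uint8)
    hist = np.bincount(pixels.ravel(), minlength=256).astype(np.float64)
    if np.count_nonzero(hist) < 2:
        raise DegenerateInputError("constant image: Otsu threshold undefined")
    total = hist.sum()
    w0 = np.cumsum(hist)  # pixels with level <= t
    s0 = np.cumsum(hist * np.arange(256))  # intensity mass with level <= t
    w1 = total - w0
    mu_total = s0[-1]
    # between-class variance w0*w1*(mu0-mu1)^2, defined only when both classes
    # are non-empty; candidate thresholds t = 0..254
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = s0 / w0
        mu1 = (mu_total - s0) / w1
        sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    sigma_b = sigma_b[:255]
    sigma_b[~np.isfinite(sigma_b)] = -np.inf
    return int(np.argmax(sigma_b))  # argmax returns the first (lowest) maximum


def strip_periphery(frame: Frame) -> CropResult:
    """Crop the frame to the bright scan region, removing the annotation rim.

    Binarizes at the Otsu threshold, labels 8-connected foreground components,
    and crops the minimum enclosing axis-aligned rectangle of the largest-area
    component.  Pixel sizes are unchanged by cropping.

    A frame with no dark periphery (e.g. one that has already been cropped)
    is returned whole: when more than 10% of the foreground lies outside the
    largest component's rectangle, the binarization has split scan content
    rather than found an annotation rim, and no crop is applied.  This makes
    the operation idempotent.

    Raises
    ------
    DegenerateInputError
        If the foreground is empty after thresholding.
    """
    t = otsu_threshold(frame.pixels)
    fg = frame.pixels > t
    if not fg.any():
        raise DegenerateInputError("empty foreground after Otsu thresholding")
    labels = _skmeasure.label(fg, connectivity=2)
    areas = np.bincount(labels.ravel())
    areas[0] = 0
    largest = int(np.argmax(areas))
    rows, cols = np.nonzero(labels == largest)
    box = (int(rows.min()), int(rows.max()), int(cols.min()), int(cols.max()))
    r0, r1, c0, c1 = box
    inside = int(fg[r0 : r1 + 1, c0 : c1 + 1].sum())
    if int(fg.sum()) - inside > 0.1 * int(fg.sum()):
        h, w = frame.shape
        box = (0, h - 1, 0, w - 1)
    r0, r1, c0, c1 = box
    cropped = Frame(
        frame.pixels[r0 : r1 + 1, c0 : c1 + 1].copy(),
        frame.pixel_size_mm,
        source_id=frame.source_id,
    )
    return CropResult(cropped=cropped, box=box)


def _resized_pixel_size(
    shape: Tuple[int, int], pixel_size_mm: Tuple[float, float], target: int
) -> Tuple[float, float]:
    # physical extent per axis is conserved: new_px = old_px * old_extent / target
    return (
        pixel_size_mm[0] * shape[0] / target,
        pixel_size_mm[1] * shape[1] / target,
    )


def resize_to_model(frame: Frame, target: int = 512) -> Frame:
    """Resize a frame to ``target x target`` with bilinear interpolation.

    The per-axis pixel size is scaled so the physical extent of the frame is
    conserved; for a non-square crop the output pixel size is anisotropic.
    """
    if target < 8:
        raise ParameterError("target size must be >= 8")
    new_ps = _resized_pixel_size(frame.shape, frame.pixel_size_mm, target)
    if frame.shape == (target, target):
        return Frame(frame.pixels.copy(), new_ps, source_id=frame.source_id)
    out = _skresize(
        frame.pixels.astype(np.float64),
        (target, target),
        order=1,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )
    out = np.clip(np.round(out), 0, 255).astype(np.uint8)
    return Frame(out, new_ps, source_id=frame.source_id)


def resize_mask_to_model(mask: BinaryMask, target: int = 512) -> BinaryMask:
    """Resize a binary mask with nearest-neighbour interpolation (stays binary)."""
    if target < 8:
        raise ParameterError("target size must be >= 8")
    new_ps = _resized_pixel_size(mask.shape, mask.pixel_size_mm, target)
    if mask.shape == (target, target):
        return BinaryMask(mask.values.copy(), new_ps)
    out = _skresize(
        mask.values,
        (target, target),
        order=0,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )
    return BinaryMask(out.astype(np.uint8), new_ps)


def save_frame_png(frame: Frame, path: Union[str, Path], sidecar: bool = True) -> None:
    """Write a frame as 8-bit grayscale PNG plus a JSON calibration sidecar."""
    path = Path(path)
    Image.fromarray(frame.pixels, mode="L").save(path)
    if sidecar:
        meta = {
            "pixel_size_mm": list(frame.pixel_size_mm),
            "source_id": frame.source_id,
            "shape": list(frame.shape),
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))
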