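"""Probability-map binarization and connected-component cleanup.

A segmentation network emits a per-pixel foreground probability map.  The two
rectus abdominis bodies appear as at most two regions, so any extra components
after thresholding are segmentation errors: the map is binarized at 0.5 and
only the two largest connected components are kept.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import List, Tuple, Union

import numpy as np
from PIL import Image
from skimage import measure as _skmeasure

from .core import BinaryMask, ParameterError, ProbMap

__all__ = ["Region", "binarize", "label_regions", "keep_two_largest",
           "save_mask_png", "load_mask_png"]


@dataclass(frozen=True)
class Region:
    """One connected component of a binary mask."""

    label: int
    area: int
    bbox: Tuple[int, int, int, int]  # row_min, row_max, col_min, col_max (inclusive)
    centroid: Tuple[float, float]  # (row, col)

    @property
    def col_min(self) -> int:
        return self.bbox[2]

    @property
    def col_max(self) -> int:
        return self.bbox[3]


def binarize(prob: ProbMap, threshold: float = 0.5) -> BinaryMask:
    """Threshold a probability map: foreground iff probability **strictly**
    exceeds ``threshold`` (a tie at exactly the threshold is background)."""
    if not (0.0 < threshold < 1.0):
        raise ParameterError("threshold must lie strictly between 0 and 1")
    return BinaryMask((prob.values > threshold).astype(np.uint8), prob.pixel_size_mm)


def _connectivity_arg(connectivity: int) -> int:
    if connectivity == 8:
        return 2
    if connectivity == 4:
        return 1
    raise ParameterError("connectivity must be 4 or 8")


def label_regions(mask: BinaryMask, connectivity: int = 8) -> List[Region]:
    """Connected components of the mask foreground, sorted by area descending;
    equal areas are ordered by smaller bounding-column first (deterministic)."""
    conn = _connectivity_arg(connectivity)
    labels = _skmeasure.label(mask.astype_bool(), connectivity=conn)
    regions: List[Region] = []
    for rp in _skmeasure.regionprops(labels):
        r0, c0, r1, c1 = rp.bbox  # skimage bbox is half-open
        regions.append(
            Region(
                label=int(rp.label),
                area=int(rp.area),
                bbox=(int(r0), int(r1) - 1, int(c0), int(c1) - 1),
                centroid=(float(rp.centroid[0]), float(rp.centroid[1])),
            )
        )
    regions.sort(key=lambda r: (-r.area, r.col_min))
    return regions


def keep_two_largest(mask: BinaryMask, connectivity: int = 8) -> BinaryMask:
    """Keep only the (at most) two largest connected components.

    Idempotent; the output foreground is a subset of the input foreground.
    Area ties are resolved toward the component with the smaller bounding
    column, matching :func:`label_regions` ordering.
    """
    conn = _connectivity_arg(connectivity)
    labels = _skmeasure.label(mask.astype_bool(), connectivity=conn)
    regions = label_regions(mask, connectivity=connectivity)
    if len(regions) <= 2:
        return BinaryMask(mask.values.copy(), mask.pixel_size_mm)
    keep = {regions[0].label, regions[1].label}
    out = np.isin(labels, list(keep)).astype(np.uint8)
    return BinaryMask(out, mask.pixel_size_mm)


def save_mask_png(mask: BinaryMask, path: Union[str, Path]) -> None:
    """Write a mask as 0/255 8-bit grayscale PNG."""
    Image.fromarray((mask.values * 255).astype(np.uint8), mode="L").save(Path(path))


def load_mask_png(
    path: Union[str, Path], pixel_size_mm: Tuple[float, float] = (1.0, 1.0)
) -> BinaryMask:
    """Read a 0/255 PNG mask back as a :class:`BinaryMask`."""
    arr = np.asarray(Image.open(Path(path)).convert("L"))
    return BinaryMask((arr > 127).astype(np.uint8), pixel_size_mm)
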