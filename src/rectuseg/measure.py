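"""Inter-muscle gap measurement and the diastasis-recti decision rule.

After post-processing, a mask holds one or two rectus abdominis regions.  With
two regions, the pixel gap ``d`` is the number of background columns strictly
between the minimum bounding rectangles of the left and the right muscle —
the lateral width of the empty corridor across the linea alba.  The physical
distance is ``D = Px * d`` where ``Px`` is the lateral (column-axis) effective
pixel size in mm after crop/resize.  Diastasis recti is called when
``D >= 25 mm`` (2.5 cm); with a single region the muscles are non-separated
and the distance is 0 by definition.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, List, Tuple, Union

import pandas as pd

from .core import BinaryMask, Measurement, ParameterError
from .postprocess import label_regions

__all__ = ["measure_distance", "classify_dra", "write_measurements_csv",
           "measurement_to_json", "DRA_THRESHOLD_MM"]

#: Clinical decision threshold: separation at >= 2.5 cm inter-muscle distance.
DRA_THRESHOLD_MM = 25.0


def measure_distance(
    mask: BinaryMask,
    connectivity: int = 8,
    dra_threshold_mm: float = DRA_THRESHOLD_MM,
    strict_threshold: bool = False,
) -> Measurement:
    """Measure the lateral gap between the two muscle regions of a mask.

    The mask must already be post-processed (at most two components).  With
    two components, left/right are identified by centroid column and

    ``d_px = col_min(right bbox) - col_max(left bbox) - 1``

    clamped at 0 when the bounding rectangles touch or overlap laterally.
    With one component the distance is 0; with none the measurement is
    flagged invalid.

    Raises
    ------
    ParameterError
        If the mask still has more than two components.
    """
    regions = label_regions(mask, connectivity=connectivity)
    if len(regions) > 2:
        raise ParameterError(
            f"mask has {len(regions)} components; apply keep_two_largest first"
        )
    px_mm = mask.pixel_size_mm[1]  # lateral axis
    if len(regions) == 0:
        return Measurement(
            d_px=0, px_mm=px_mm, D_mm=0.0, n_regions=0,
            dra_separated=False, valid=False, dra_threshold_mm=dra_threshold_mm,
        )
    if len(regions) == 1:
        d_px = 0
    else:
        left, right = sorted(regions, key=lambda r: r.centroid[1])
        d_px = max(0, right.col_min - left.col_max - 1)
    D_mm = px_mm * d_px
    separated = (D_mm > dra_threshold_mm) if strict_threshold else (D_mm >= dra_threshold_mm)
    return Measurement(
        d_px=d_px, px_mm=px_mm, D_mm=D_mm, n_regions=len(regions),
        dra_separated=separated, valid=True, dra_threshold_mm=dra_threshold_mm,
    )


def classify_dra(m: Measurement) -> str:
    """Classify a measurement as ``separated`` / ``non-separated`` / ``invalid``."""
    if not m.valid:
        return "invalid"
    return "separated" if m.dra_separated else "non-separated"


def measurement_to_json(m: Measurement, source_id: str = "") -> str:
    return json.dumps(
        {
            "source_id": source_id,
            "d_px": m.d_px,
            "px_mm": m.px_mm,
            "D_mm": m.D_mm,
            "n_regions": m.n_regions,
            "label": classify_dra(m),
            "valid": m.valid,
        }
    )


def write_measurements_csv(
    records: Iterable[Tuple[str, Measurement]], path: Union[str, Path]
) -> pd.DataFrame:
    """Write a batch of per-image measurements as CSV; returns the table."""
    rows: List[dict] = []
    for source_id, m in records:
        rows.append(
            {
                "source_id": source_id,
                "d_px": m.d_px,
                "px_mm": m.px_mm,
                "D_mm": m.D_mm,
                "n_regions": m.n_regions,
                "label": classify_dra(m),
                "valid": m.valid,
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(Path(path), index=False)
    return df
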