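"""Segmentation-quality and method-agreement metrics.

Overlap metrics compare a predicted mask A against a ground-truth mask B:

* Dice = 2|A∩B| / (|A| + |B|), in percent;
* IoU  = |A∩B| / |A∪B|, in percent (the single-foreground-class form; a
  two-class foreground/background mean is available behind a flag);
* Hausdorff distance HD = max(h(A,B), h(B,A)) with h the directed
  max-over-pixels of the shortest Euclidean distance to the other set,
  computed in mm over the full foreground point sets using the per-axis
  pixel sizes.

Distance agreement between automatic and manual gap measurements uses the
average physical distance error APDE = mean_i p_i * |d_i - d̂_i| (mm), the
sample Pearson correlation, and Bland–Altman limits of agreement
mean ± 1.96·sd of the paired differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage as _ndi

from .core import BinaryMask, DegenerateInputError, ParameterError, ShapeError

__all__ = [
    "dice",
    "miou",
    "hausdorff_mm",
    "apde",
    "pearson_r",
    "bland_altman",
    "EvalReport",
    "evaluate_masks",
    "aggregate_mean_sd",
]


def _fg_pair(A: BinaryMask, B: BinaryMask) -> Tuple[np.ndarray, np.ndarray]:
    a, b = A.astype_bool(), B.astype_bool()
    if a.shape != b.shape:
        raise ShapeError(f"mask shapes differ: {a.shape} vs {b.shape}")
    return a, b


def dice(A: BinaryMask, B: BinaryMask) -> float:
    """Dice overlap in percent; symmetric. Two empty masks agree perfectly
    (100) — callers that care should flag the empty-empty case."""
    a, b = _fg_pair(A, B)
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        return 100.0
    return 200.0 * int((a & b).sum()) / (na + nb)


def miou(A: BinaryMask, B: BinaryMask, two_class: bool = False) -> float:
    """Intersection-over-union in percent.

    By default the single-foreground-class IoU |A∩B|/|A∪B|; with
    ``two_class=True`` the mean of foreground and background IoU.
    """
    a, b = _fg_pair(A, B)
    union = int((a | b).sum())
    inter = int((a & b).sum())
    fg = 100.0 if union == 0 else 100.0 * inter / union
    if not two_class:
        return fg
    ai, bi = ~a, ~b
    union_bg = int((ai | bi).sum())
    inter_bg = int((ai & bi).sum())
    bg = 100.0 if union_bg == 0 else 100.0 * inter_bg / union_bg
    return 0.5 * (fg + bg)


def hausdorff_mm(A: BinaryMask, B: BinaryMask) -> float:
    """Symmetric Hausdorff distance between foreground point sets, in mm.

    Computed with exact Euclidean distance transforms using the masks' shared
    per-axis pixel size, equivalent to the brute-force max-min over all
    foreground pixel pairs.

    Raises
    ------
    DegenerateInputError
        If either mask is empty (the distance is undefined).
    """
    a, b = _fg_pair(A, B)
    if A.pixel_size_mm != B.pixel_size_mm:
        raise ShapeError("masks carry different pixel sizes")
    if not a.any() or not b.any():
        raise DegenerateInputError("Hausdorff distance undefined for an empty mask")
    sampling = A.pixel_size_mm
    dist_to_b = _ndi.distance_transform_edt(~b, sampling=sampling)
    dist_to_a = _ndi.distance_transform_edt(~a, sampling=sampling)
    h_ab = float(dist_to_b[a].max())  # furthest A pixel from B
    h_ba = float(dist_to_a[b].max())
    return max(h_ab, h_ba)


def apde(records: Sequence[Mapping[str, float]]) -> float:
    """Average physical distance error in mm.

    Each record carries ``d_manual_px``, ``d_pred_px`` and ``px_mm``; APDE is
    the mean over records of ``px_mm * |d_manual_px - d_pred_px|``.
    """
    if len(records) == 0:
        raise ParameterError("APDE requires at least one record")
    errs = []
    for r in records:
        p = float(r["px_mm"])
        if p <= 0:
            raise ParameterError("px_mm must be positive")
        errs.append(p * abs(float(r["d_manual_px"]) - float(r["d_pred_px"])))
    return float(np.mean(errs))


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson correlation coefficient."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ShapeError("x and y must be 1-D of equal length")
    if x.size < 3:
        raise ParameterError("need at least 3 paired values")
    xc, yc = x - x.mean(), y - y.mean()
    sx, sy = np.sqrt((xc**2).sum()), np.sqrt((yc**2).sum())
    if sx == 0 or sy == 0:
        raise DegenerateInputError("constant input vector: correlation undefined")
    return float(np.clip((xc * yc).sum() / (sx * sy), -1.0, 1.0))


def bland_altman(x: Sequence[float], y: Sequence[float]) -> Dict[str, float]:
    """Bland–Altman agreement statistics of paired measurements.

    Returns the mean difference ``mean(y - x)`` and the 95% limits of
    agreement ``mean ± 1.96·sd`` (sample sd, n-1 denominator).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ShapeError("x and y must be 1-D of equal length")
    if x.size < 3:
        raise ParameterError("need at least 3 paired values")
    d = y - x
    mean_diff = float(d.mean())
    sd = float(d.std(ddof=1))
    return {
        "mean_diff": mean_diff,
        "loa_low": mean_diff - 1.96 * sd,
        "loa_high": mean_diff + 1.96 * sd,
    }


@dataclass
class EvalReport:
    """Per-image and aggregate evaluation of a set of predicted masks."""

    per_image: List[Dict[str, float]] = field(default_factory=list)
    aggregates: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    apde_mm: Optional[float] = None
    pearson: Optional[float] = None
    bland_altman: Optional[Dict[str, float]] = None

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.per_image)


def evaluate_masks(
    preds: Sequence[BinaryMask],
    gts: Sequence[BinaryMask],
    d_pred_px: Optional[Sequence[int]] = None,
    d_manual_px: Optional[Sequence[int]] = None,
    ids: Optional[Sequence[str]] = None,
) -> EvalReport:
    """Evaluate predicted against ground-truth masks, image by image.

    Computes Dice/IoU/HD per image (HD recorded as NaN when either mask is
    empty) and, when pixel gap measurements are supplied, the APDE, Pearson
    correlation and Bland–Altman agreement between automatic and manual
    physical distances.
    """
    if len(preds) != len(gts):
        raise ShapeError("prediction and ground-truth lists differ in length")
    report = EvalReport()
    for i, (p, g) in enumerate(zip(preds, gts)):
        rec: Dict[str, float] = {
            "id": ids[i] if ids is not None else str(i),  # type: ignore[dict-item]
            "dice_pct": dice(p, g),
            "iou_pct": miou(p, g),
            "empty_pair": float(not p.astype_bool().any() and not g.astype_bool().any()),
        }
        try:
            rec["hd_mm"] = hausdorff_mm(p, g)
        except DegenerateInputError:
            rec["hd_mm"] = float("nan")
        if d_pred_px is not None and d_manual_px is not None:
            px = p.pixel_size_mm[1]
            rec["d_pred_px"] = float(d_pred_px[i])
            rec["d_manual_px"] = float(d_manual_px[i])
            rec["abs_dist_err_mm"] = px * abs(d_pred_px[i] - d_manual_px[i])
        report.per_image.append(rec)

    for key in ("dice_pct", "iou_pct", "hd_mm", "abs_dist_err_mm"):
        vals = np.array([r[key] for r in report.per_image if key in r], dtype=float)
        vals = vals[np.isfinite(vals)]
        if vals.size:
            sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
            report.aggregates[key] = (float(vals.mean()), sd)

    if d_pred_px is not None and d_manual_px is not None and len(preds) >= 1:
        recs = [
            {
                "d_manual_px": d_manual_px[i],
                "d_pred_px": d_pred_px[i],
                "px_mm": preds[i].pixel_size_mm[1],
            }
            for i in range(len(preds))
        ]
        report.apde_mm = apde(recs)
        if len(preds) >= 3:
            x = [r["px_mm"] * r["d_manual_px"] for r in recs]
            y = [r["px_mm"] * r["d_pred_px"] for r in recs]
            try:
                report.pearson = pearson_r(x, y)
            except DegenerateInputError:
                report.pearson = None
            report.bland_altman = bland_altman(x, y)
    return report


def aggregate_mean_sd(values: Iterable[float]) -> Tuple[float, float]:
    """Mean ± sd (n-1) over repeated runs, the repeat-aggregation convention."""
    v = np.asarray(list(values), dtype=np.float64)
    if v.size == 0:
        raise ParameterError("no values to aggregate")
    return float(v.mean()), (float(v.std(ddof=1)) if v.size > 1 else 0.0)
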