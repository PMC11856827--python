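"""Boundary-distance and tip evaluation for thin tubular segmentations.

A catheter is better characterized by its boundary than by its area, so the
primary course metric here is the average symmetric surface distance (ASSD):
the mean, over both boundaries, of each boundary point's shortest Euclidean
distance (in mm) to the other boundary,

    ASSD(B1, B2) = [ sum_{x in B1} d(x, B2) + sum_{y in B2} d(y, B1) ]
                   / (|B1| + |B2|).

The tip is the most inferior foreground pixel of the catheter mask, and the
tip distance is the spacing-adjusted Euclidean distance between predicted
and true tips. The Dice similarity coefficient is provided for comparison
with overlap-based literature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import AggregationError, EmptyMaskError, GeometryError
from .raster import BinaryMask, PointRC

__all__ = [
    "EvalRecord",
    "boundary",
    "boundary_mask",
    "assd",
    "dsc",
    "extract_tip",
    "tip_distance",
    "summarize",
]

_CROSS = ndimage.generate_binary_structure(2, 1)


@dataclass
class EvalRecord:
    """Per-sample, per-method evaluation row."""

    sample_id: str
    method_label: str
    assd_mm: float
    tip_distance_mm: float
    dsc: float

    def __post_init__(self) -> None:
        if self.assd_mm < 0 or self.tip_distance_mm < 0 or not 0 <= self.dsc <= 1:
            raise GeometryError("metrics out of range")


def boundary_mask(mask: BinaryMask) -> np.ndarray:
    """Boolean array of boundary pixels: foreground with a background
    4-neighbor, the image border counting as background."""
    if mask.is_empty:
        raise EmptyMaskError("boundary of an empty mask")
    interior = ndimage.binary_erosion(mask.values, structure=_CROSS, border_value=0)
    return mask.values & ~interior


def boundary(mask: BinaryMask) -> set[PointRC]:
    """Boundary pixels of a mask as a set of integer points."""
    rows, cols = np.nonzero(boundary_mask(mask))
    return {PointRC(int(r), int(c)) for r, c in zip(rows, cols)}


def _check_compatible(pred: BinaryMask, truth: BinaryMask) -> None:
    if pred.shape != truth.shape:
        raise GeometryError(f"shape mismatch {pred.shape} vs {truth.shape}")
    if pred.spacing_mm != truth.spacing_mm:
        raise GeometryError(f"spacing mismatch {pred.spacing_mm} vs {truth.spacing_mm}")


def assd(pred: BinaryMask, truth: BinaryMask) -> float:
    """Average symmetric surface distance between two masks, in mm.

    Computed with the Euclidean distance transform sampled at boundary
    pixels; indices are scaled by spacing before taking distances.
    """
    _check_compatible(pred, truth)
    if pred.is_empty or truth.is_empty:
        raise EmptyMaskError("ASSD is undefined for an empty mask")
    b1 = boundary_mask(pred)
    b2 = boundary_mask(truth)
    d_to_b2 = ndimage.distance_transform_edt(~b2, sampling=pred.spacing_mm)
    d_to_b1 = ndimage.distance_transform_edt(~b1, sampling=pred.spacing_mm)
    total = d_to_b2[b1].sum() + d_to_b1[b2].sum()
    return float(total / (b1.sum() + b2.sum()))


def dsc(pred: BinaryMask, truth: BinaryMask) -> float:
    """Dice similarity coefficient 2|A.B| / (|A| + |B|); both empty -> 1."""
    if pred.shape != truth.shape:
        raise GeometryError(f"shape mismatch {pred.shape} vs {truth.shape}")
    a, b = pred.count, truth.count
    if a + b == 0:
        return 1.0
    inter = int((pred.values & truth.values).sum())
    return 2.0 * inter / (a + b)


def extract_tip(mask: BinaryMask) -> PointRC:
    """Most inferior point of the mask: the maximal foreground row, with the
    median column of the pixels on that row (deterministic under stroke
    thickness)."""
    if mask.is_empty:
        raise EmptyMaskError("extract_tip of an empty mask")
    rows, cols = np.nonzero(mask.values)
    max_row = int(rows.max())
    at_max = np.sort(cols[rows == max_row])
    med = float(np.median(at_max))
    return PointRC(max_row, int(math.floor(med + 0.5)))


def tip_distance(tip_a: PointRC, tip_b: PointRC, spacing_mm: tuple[float, float]) -> float:
    """Euclidean distance between two tips, adjusted by pixel spacing (mm)."""
    return float(
        math.hypot(
            (tip_a.row - tip_b.row) * spacing_mm[0],
            (tip_a.col - tip_b.col) * spacing_mm[1],
        )
    )


def summarize(records: list[EvalRecord]) -> dict[str, dict[str, dict[str, float]]]:
    """Per-method mean, sample SD and normal 95% CI for each metric.

    Returns ``{method: {metric: {mean, sd, ci_low, ci_high, n}}}`` with
    CI = mean +/- 1.96 * SD / sqrt(n). Requires >= 2 records per method.
    """
    groups: dict[str, list[EvalRecord]] = {}
    for rec in records:
        groups.setdefault(rec.method_label, []).append(rec)
    if not groups:
        raise AggregationError("no records to summarize")
    out: dict[str, dict[str, dict[str, float]]] = {}
    for method in sorted(groups):
        rows = groups[method]
        if len(rows) < 2:
            raise AggregationError(f"method {method!r} has fewer than 2 records")
        out[method] = {}
        for metric in ("assd_mm", "tip_distance_mm", "dsc"):
            # sorted so the summary is bitwise independent of record order
            vals = np.sort(np.array([getattr(r, metric) for r in rows], dtype=float))
            mean = float(vals.mean())
            sd = float(vals.std(ddof=1))
            half = 1.96 * sd / math.sqrt(len(vals))
            out[method][metric] = {
                "mean": mean,
                "sd": sd,
                "ci_low": mean - half,
                "ci_high": mean + half,
                "n": float(len(vals)),
            }
    return out
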