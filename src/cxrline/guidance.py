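"""Trachea-landmark spatial reasoning: search-region definition, cropping
and restoration of predictions to the original image scale.

The right internal jugular line (RIJL) descends on the patient's right of
the trachea, so a fixed-size physical search box (default 300 mm tall by
150 mm wide) anchored on the trachea centroid isolates the region where the
catheter can plausibly lie. A crop footprint records everything needed to
put a cropped prediction back into original image coordinates exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import GeometryError, ParameterError
from .raster import BinaryMask, PointRC, RasterGrid, largest_component

__all__ = [
    "SearchBoxSpec",
    "BoundingBox",
    "CropFootprint",
    "trachea_roi",
    "define_search_region",
    "crop",
    "restore_to_original",
]

PATIENT_RIGHT = "patient_right"
PATIENT_LEFT = "patient_left"
STANDARD_AP = "standard_AP"
MIRRORED = "mirrored"


@dataclass
class SearchBoxSpec:
    """Physical dimensions and anchoring of the RIJL search box.

    ``vertical_anchor_fraction`` places the top edge of the box that
    fraction of the box height above the trachea centroid (default 1/3:
    the catheter course runs mostly inferior to mid-trachea).
    Under ``standard_AP`` display the patient's right is toward decreasing
    column indices (viewer's left).
    """

    height_mm: float = 300.0
    width_mm: float = 150.0
    laterality: str = PATIENT_RIGHT
    vertical_anchor_fraction: float = 1.0 / 3.0
    display_convention: str = STANDARD_AP

    def __post_init__(self) -> None:
        if self.height_mm <= 0 or self.width_mm <= 0:
            raise ParameterError("search box dimensions must be positive")
        if not 0.0 <= self.vertical_anchor_fraction <= 1.0:
            raise ParameterError("vertical_anchor_fraction must lie in [0, 1]")
        if self.laterality not in (PATIENT_RIGHT, PATIENT_LEFT):
            raise ParameterError(f"unknown laterality {self.laterality!r}")
        if self.display_convention not in (STANDARD_AP, MIRRORED):
            raise ParameterError(f"unknown display convention {self.display_convention!r}")


@dataclass(frozen=True)
class BoundingBox:
    """Half-open pixel box [row_min, row_max) x [col_min, col_max)."""

    row_min: int
    row_max: int
    col_min: int
    col_max: int

    def __post_init__(self) -> None:
        if self.row_min >= self.row_max or self.col_min >= self.col_max:
            raise GeometryError(f"degenerate box {self}")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.row_max - self.row_min, self.col_max - self.col_min)

    def clip(self, shape: tuple[int, int]) -> "BoundingBox":
        r0 = max(self.row_min, 0)
        r1 = min(self.row_max, shape[0])
        c0 = max(self.col_min, 0)
        c1 = min(self.col_max, shape[1])
        if r0 >= r1 or c0 >= c1:
            raise GeometryError(f"box {self} falls entirely outside grid {shape}")
        return BoundingBox(r0, r1, c0, c1)


@dataclass
class CropFootprint:
    """Record of a crop: upper-right vertex + box dimensions + original shape.

    Sufficient to restore a cropped prediction to the original scale.
    """

    upper_right_vertex: PointRC
    box_dims: tuple[int, int]
    original_shape: tuple[int, int]
    spacing_mm: tuple[float, float]

    @property
    def bbox(self) -> BoundingBox:
        r0 = int(self.upper_right_vertex.row)
        c1 = int(self.upper_right_vertex.col) + 1
        h, w = self.box_dims
        return BoundingBox(r0, r0 + h, c1 - w, c1)

    def to_json(self) -> str:
        return json.dumps(
            {
                "upper_right_vertex": [int(self.upper_right_vertex.row),
                                       int(self.upper_right_vertex.col)],
                "box_dims": list(self.box_dims),
                "original_shape": list(self.original_shape),
                "spacing_mm": list(self.spacing_mm),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "CropFootprint":
        d = json.loads(text)
        return cls(
            upper_right_vertex=PointRC(*d["upper_right_vertex"]),
            box_dims=tuple(d["box_dims"]),
            original_shape=tuple(d["original_shape"]),
            spacing_mm=tuple(d["spacing_mm"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "CropFootprint":
        return cls.from_json(Path(path).read_text())


def trachea_roi(trachea_mask: BinaryMask) -> BinaryMask:
    """Largest connected component of the trachea landmark segmentation.

    Raises EmptyMaskError on an empty mask, which signals that the upstream
    trachea segmentation failed.
    """
    return largest_component(trachea_mask)


def define_search_region(
    trachea_centroid: PointRC,
    grid: RasterGrid | BinaryMask,
    spec: SearchBoxSpec | None = None,
) -> BoundingBox:
    """Place the physical search box on the pixel grid and clip it.

    The box is ``height_mm`` x ``width_mm`` converted to pixels via the grid
    spacing. Its medial edge sits at the trachea centroid column and it
    extends toward the configured patient side; vertically the top edge sits
    ``vertical_anchor_fraction`` of the height above the centroid.
    """
    spec = spec or SearchBoxSpec()
    rows, cols = grid.shape
    if not (0 <= trachea_centroid.row < rows and 0 <= trachea_centroid.col < cols):
        raise GeometryError(f"centroid {trachea_centroid} outside grid {grid.shape}")
    sr, sc = grid.spacing_mm
    height_px = int(round(spec.height_mm / sr))
    width_px = int(round(spec.width_mm / sc))
    r0 = int(round(trachea_centroid.row - spec.vertical_anchor_fraction * height_px))
    r1 = r0 + height_px
    c_ref = int(round(trachea_centroid.col))
    toward_right_is_decreasing = spec.display_convention == STANDARD_AP
    extends_decreasing = (spec.laterality == PATIENT_RIGHT) == toward_right_is_decreasing
    if extends_decreasing:
        c0, c1 = c_ref - width_px + 1, c_ref + 1
    else:
        c0, c1 = c_ref, c_ref + width_px
    return BoundingBox(r0, r1, c0, c1).clip((rows, cols))


def crop(
    grid_or_mask: RasterGrid | BinaryMask, bbox: BoundingBox
) -> tuple[RasterGrid | BinaryMask, CropFootprint]:
    """Extract the box as a subimage; return it with its restore footprint."""
    rows, cols = grid_or_mask.shape
    if not (0 <= bbox.row_min < bbox.row_max <= rows and 0 <= bbox.col_min < bbox.col_max <= cols):
        raise GeometryError(f"box {bbox} not contained in grid {grid_or_mask.shape}")
    sub = grid_or_mask.values[bbox.row_min : bbox.row_max, bbox.col_min : bbox.col_max]
    footprint = CropFootprint(
        upper_right_vertex=PointRC(bbox.row_min, bbox.col_max - 1),
        box_dims=bbox.shape,
        original_shape=(rows, cols),
        spacing_mm=grid_or_mask.spacing_mm,
    )
    if isinstance(grid_or_mask, BinaryMask):
        out = grid_or_mask.with_values(sub.copy())
    else:
        out = RasterGrid(sub.copy(), grid_or_mask.spacing_mm)
    return out, footprint


def restore_to_original(cropped_mask: BinaryMask, footprint: CropFootprint) -> BinaryMask:
    """Embed a cropped prediction back into the original image frame."""
    if cropped_mask.shape != tuple(footprint.box_dims):
        raise GeometryError(
            f"cropped mask shape {cropped_mask.shape} != footprint dims {footprint.box_dims}"
        )
    full = np.zeros(footprint.original_shape, dtype=bool)
    b = footprint.bbox
    full[b.row_min : b.row_max, b.col_min : b.col_max] = cropped_mask.values
    return BinaryMask(full, footprint.spacing_mm, cropped_mask.connectivity)
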