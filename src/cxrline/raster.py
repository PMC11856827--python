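"""Grid/mask data model, I/O and low-level binary morphology.

Conventions used throughout the package:

* Pixels are addressed as 0-based ``(row, col)``; row 0 is the superior
  (cranial) image edge and the row index increases inferiorly.
* The physical position of pixel ``(r, c)`` is ``(r * row_spacing_mm,
  c * col_spacing_mm)``.
* Binary masks carry their connectivity convention (4 or 8 adjacency);
  8 is the default so that thin diagonal strokes do not fragment.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import NamedTuple

import nibabel as nib
import numpy as np
from imageio.v3 import imread, imwrite
from scipy import ndimage
from skimage.measure import label as sk_label
from skimage.morphology import skeletonize as sk_skeletonize

from .errors import (
    ConfigurationError,
    EmptyMaskError,
    FormatError,
    ParameterError,
)

__all__ = [
    "PointRC",
    "RasterGrid",
    "BinaryMask",
    "read_mask",
    "write_mask",
    "connected_components",
    "largest_component",
    "centroid",
    "skeletonize",
    "dilate_disk",
]


class PointRC(NamedTuple):
    """A (row, col) location; integer when designating a pixel."""

    row: float
    col: float


@dataclass
class RasterGrid:
    """A 2-D scalar lattice with per-axis pixel spacing in millimetres."""

    values: np.ndarray
    spacing_mm: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2 or min(self.values.shape) < 1:
            raise FormatError(f"expected a 2-D grid, got shape {self.values.shape}")
        sr, sc = self.spacing_mm
        if not (sr > 0 and sc > 0):
            raise ParameterError(f"spacings must be positive, got {self.spacing_mm}")
        self.spacing_mm = (float(sr), float(sc))

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class BinaryMask:
    """A RasterGrid whose values are {0, 1}, with a fixed adjacency rule.

    ``connectivity`` is 4 or 8 and is inherited by every mask derived from
    this one (components, skeletons, dilations, crops).
    """

    values: np.ndarray
    spacing_mm: tuple[float, float] = (1.0, 1.0)
    connectivity: int = 8

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if arr.ndim != 2 or min(arr.shape) < 1:
            raise FormatError(f"expected a 2-D mask, got shape {arr.shape}")
        if arr.dtype != bool and not np.isin(arr, (0, 1)).all():
            raise FormatError("mask values must all be 0 or 1")
        self.values = arr.astype(bool)
        sr, sc = self.spacing_mm
        if not (sr > 0 and sc > 0):
            raise ParameterError(f"spacings must be positive, got {self.spacing_mm}")
        self.spacing_mm = (float(sr), float(sc))
        if self.connectivity not in (4, 8):
            raise ParameterError(f"connectivity must be 4 or 8, got {self.connectivity}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def count(self) -> int:
        """Number of foreground pixels."""
        return int(self.values.sum())

    @property
    def is_empty(self) -> bool:
        return not self.values.any()

    def with_values(self, values: np.ndarray) -> "BinaryMask":
        """A new mask on the same grid (spacing/connectivity inherited)."""
        return BinaryMask(values, self.spacing_mm, self.connectivity)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BinaryMask):
            return NotImplemented
        return (
            self.shape == other.shape
            and self.spacing_mm == other.spacing_mm
            and bool((self.values == other.values).all())
        )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_mask(
    path: str | Path,
    spacing_override: tuple[float, float] | None = None,
    connectivity: int = 8,
) -> BinaryMask:
    """Read a binary mask from PNG (8-bit, foreground > 0) or NIfTI.

    PNG carries no physical spacing, so ``spacing_override`` is required for
    it; NIfTI spacing is taken from the header ``pixdim`` unless overridden.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix == ".png":
        if spacing_override is None:
            raise ConfigurationError(
                f"PNG has no spacing metadata; pass spacing_override for {path}"
            )
        arr = imread(path)
        if arr.ndim == 3:  # collapse accidental RGB(A) export
            arr = arr[..., 0]
        return BinaryMask(arr > 0, spacing_override, connectivity)
    if path.name.endswith((".nii", ".nii.gz")):
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        data = np.squeeze(data)
        if data.ndim != 2:
            raise FormatError(f"{path}: expected a 2-D NIfTI volume, got {data.ndim}-D")
        spacing = spacing_override or tuple(float(z) for z in img.header.get_zooms()[:2])
        return BinaryMask(data > 0, spacing, connectivity)
    raise FormatError(f"unsupported mask format: {path}")


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    """Write a mask as PNG (0/255) or NIfTI (spacing in the header)."""
    path = Path(path)
    if path.suffix == ".png":
        imwrite(path, (mask.values.astype(np.uint8) * 255))
    elif path.name.endswith((".nii", ".nii.gz")):
        affine = np.diag([mask.spacing_mm[0], mask.spacing_mm[1], 1.0, 1.0])
        img = nib.Nifti1Image(mask.values.astype(np.uint8), affine)
        img.header.set_zooms(mask.spacing_mm)
        nib.save(img, str(path))
    else:
        raise FormatError(f"unsupported mask format: {path}")


# ---------------------------------------------------------------------------
# Connected components
# ---------------------------------------------------------------------------

def _sk_connectivity(connectivity: int) -> int:
    # scikit-image: 1 = edge (4-adjacency), 2 = edge+vertex (8-adjacency)
    return 1 if connectivity == 4 else 2


def label_components(mask: BinaryMask) -> tuple[np.ndarray, int]:
    """Label map under the mask's own adjacency rule (0 = background)."""
    labels, n = sk_label(
        mask.values, connectivity=_sk_connectivity(mask.connectivity), return_num=True
    )
    return labels, int(n)


def connected_components(mask: BinaryMask) -> list[BinaryMask]:
    """Partition the foreground into its connected components.

    Components are returned ordered by their seed pixel (the lexicographically
    smallest (row, col) they contain), so the output is deterministic.
    """
    labels, n = label_components(mask)
    comps = [mask.with_values(labels == i) for i in range(1, n + 1)]
    comps.sort(key=lambda m: _seed_pixel(m.values))
    return comps


def _seed_pixel(values: np.ndarray) -> tuple[int, int]:
    rows, cols = np.nonzero(values)
    i = np.lexsort((cols, rows))[0]
    return int(rows[i]), int(cols[i])


def largest_component(mask: BinaryMask) -> BinaryMask:
    """The component with the most pixels; ties go to the smallest seed pixel."""
    if mask.is_empty:
        raise EmptyMaskError("largest_component of an empty mask")
    labels, n = label_components(mask)
    sizes = np.bincount(labels.ravel())[1:]
    best = np.flatnonzero(sizes == sizes.max()) + 1
    if len(best) > 1:
        best = sorted(best, key=lambda i: _seed_pixel(labels == i))
    return mask.with_values(labels == best[0])


def centroid(mask: BinaryMask) -> PointRC:
    """Arithmetic mean of foreground pixel indices (continuous)."""
    if mask.is_empty:
        raise EmptyMaskError("centroid of an empty mask")
    rows, cols = np.nonzero(mask.values)
    return PointRC(float(rows.mean()), float(cols.mean()))


# ---------------------------------------------------------------------------
# Morphology
# ---------------------------------------------------------------------------

def skeletonize(mask: BinaryMask) -> BinaryMask:
    """Thin the mask to a one-pixel-wide, topology-preserving centerline."""
    if mask.is_empty:
        raise EmptyMaskError("skeletonize of an empty mask")
    return mask.with_values(sk_skeletonize(mask.values))


def dilate_disk(mask: BinaryMask, radius_px: float) -> BinaryMask:
    """Euclidean dilation: turn on every pixel within ``radius_px`` of the
    foreground. Radius 0 is the identity. Exact, via the distance transform."""
    if radius_px < 0:
        raise ParameterError(f"dilation radius must be >= 0, got {radius_px}")
    if radius_px == 0 or mask.is_empty:
        return mask.with_values(mask.values.copy())
    dist = ndimage.distance_transform_edt(~mask.values)
    return mask.with_values(dist <= radius_px + 1e-9)
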