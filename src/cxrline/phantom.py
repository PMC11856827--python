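"""Seeded synthetic phantoms for catheter-segmentation postprocessing.

Each phantom emulates the mask-level structure of a portable AP chest
radiograph with a right internal jugular line (RIJL):

* a near-midline trachea blob in the upper half of the image (the
  anatomical landmark used to define the search region);
* a thin, smoothly descending catheter curve starting superior-lateral on
  the patient-right side and curving medially to a defined inferior tip
  (the ground truth);
* a degraded "CNN-style" prediction: the ground-truth curve cut by a few
  gaps, plus distractor tubular structures (e.g. a contralateral line) at a
  guaranteed minimum offset from the catheter trajectory.

Everything is deterministic given the seed. Phantoms are mask-level:
optional grayscale rendering is decorative and never consumed by the
algorithms.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.draw import ellipse as draw_ellipse
from skimage.draw import line as bresenham_line

from .errors import GeometryError, ParameterError
from .metrics import extract_tip
from .raster import (
    BinaryMask,
    PointRC,
    RasterGrid,
    dilate_disk,
    label_components,
    read_mask,
    skeletonize,
    write_mask,
)
from .connect import _geodesic_hops, skeleton_endpoints

__all__ = [
    "PhantomParams",
    "PhantomSample",
    "generate_phantom",
    "fragment_mask",
    "write_phantom_set",
    "load_phantom_set",
]


@dataclass
class PhantomParams:
    """Generator knobs; defaults give a 512 mm square field at 1 mm spacing,
    a 3 px catheter stroke, two 5-20 px gaps and one contralateral
    distractor at >= 60 mm from the catheter trajectory."""

    shape_px: tuple[int, int] = (512, 512)
    spacing_mm: tuple[float, float] = (1.0, 1.0)
    line_width_px: int = 3
    n_gaps: int = 2
    gap_len_px_range: tuple[int, int] = (5, 20)
    n_distractors: int = 1
    distractor_offset_mm: float = 60.0
    curve_wobble: float = 0.15
    seed: int = 0
    protect_tip: bool = True
    render_image: bool = False

    def __post_init__(self) -> None:
        lo, hi = self.gap_len_px_range
        if lo <= 0 or lo > hi:
            raise ParameterError(f"invalid gap length range {self.gap_len_px_range}")
        if self.n_gaps < 0 or self.n_distractors < 0:
            raise ParameterError("counts must be nonnegative")
        if self.line_width_px < 1:
            raise ParameterError("line_width_px must be >= 1")
        if self.distractor_offset_mm <= 0:
            raise ParameterError("distractor_offset_mm must be positive")
        if self.curve_wobble < 0:
            raise ParameterError("curve_wobble must be >= 0")


@dataclass
class PhantomSample:
    """One generated phantom: ground truth, degraded prediction, landmark."""

    gt_mask: BinaryMask
    prediction: BinaryMask
    trachea_mask: BinaryMask
    true_tip: PointRC
    params: PhantomParams
    image: RasterGrid | None = None


def _smoothstep(t: np.ndarray) -> np.ndarray:
    return t * t * (3 - 2 * t)


def _rasterize_polyline(points: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Burn an integer polyline into a boolean canvas (8-connected)."""
    canvas = np.zeros(shape, dtype=bool)
    pts = np.round(points).astype(int)
    pts[:, 0] = np.clip(pts[:, 0], 0, shape[0] - 1)
    pts[:, 1] = np.clip(pts[:, 1], 0, shape[1] - 1)
    for (r0, c0), (r1, c1) in zip(pts[:-1], pts[1:]):
        rr, cc = bresenham_line(r0, c0, r1, c1)
        canvas[rr, cc] = True
    canvas[pts[-1, 0], pts[-1, 1]] = True
    return canvas


def _wobble(t: np.ndarray, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth lateral deviation: a few random-phase low-frequency modes."""
    out = np.zeros_like(t)
    for k in (1, 2, 3):
        out += rng.normal(0, 1) / k * np.sin(np.pi * k * t + rng.uniform(0, 2 * np.pi))
    return amplitude * out


def _catheter_path(
    shape: tuple[int, int], midline_col: float, wobble: float, rng: np.random.Generator
) -> np.ndarray:
    """Continuous (row, col) samples of the RIJL course, superior to tip.

    Patient-right is toward decreasing columns under standard AP display.
    """
    rows, cols = shape
    r_start = (0.08 + 0.03 * rng.uniform(-1, 1)) * rows
    r_tip = (0.68 + 0.04 * rng.uniform(-1, 1)) * rows
    c_start = midline_col - (0.22 + 0.04 * rng.uniform(-1, 1)) * cols
    c_tip = midline_col - (0.06 + 0.02 * rng.uniform(-1, 1)) * cols
    t = np.linspace(0.0, 1.0, 200)
    r = r_start + (r_tip - r_start) * t
    c = c_start + (c_tip - c_start) * _smoothstep(t)
    c = c + _wobble(t, wobble * 0.15 * cols, rng)
    return np.column_stack([r, c])


def _distractor_path(
    shape: tuple[int, int], base_col: float, tip_row: float, rng: np.random.Generator
) -> np.ndarray:
    """A short near-vertical contralateral tube segment.

    It emulates a partial CNN response to another line: smaller than any
    catheter fragment (so the largest-component anchor stays on the
    catheter) but crossing the catheter's tip latitude, so a naive
    most-inferior-point tip lands on it.
    """
    rows, _ = shape
    r0 = tip_row - rng.uniform(20, 40) / 512 * rows
    r1 = min(tip_row + rng.uniform(25, 45) / 512 * rows, 0.95 * rows)
    t = np.linspace(0.0, 1.0, 80)
    r = r0 + (r1 - r0) * t
    c = base_col + 6 * np.sin(np.pi * t + rng.uniform(0, 2 * np.pi))
    return np.column_stack([r, c])


def generate_phantom(params: PhantomParams | None = None) -> PhantomSample:
    """Generate one phantom sample, fully deterministic given the seed."""
    params = params or PhantomParams()
    rng = np.random.default_rng(params.seed)
    shape = tuple(params.shape_px)
    rows, cols = shape
    spacing = params.spacing_mm
    stroke_radius = (params.line_width_px - 1) / 2.0

    midline = cols / 2 + rng.uniform(-0.02, 0.02) * cols

    # trachea: vertical ellipse at the column midline, upper half
    trachea = np.zeros(shape, dtype=bool)
    rr, cc = draw_ellipse(
        int(0.27 * rows), int(midline), int(0.15 * rows), int(0.025 * cols), shape=shape
    )
    trachea[rr, cc] = True
    trachea_mask = BinaryMask(trachea, spacing)

    # ground-truth catheter course
    path = _catheter_path(shape, midline, params.curve_wobble, rng)
    if (path[:, 0] < 0).any() or (path[:, 0] >= rows).any() or (
        path[:, 1] < 0
    ).any() or (path[:, 1] >= cols).any():
        raise GeometryError("catheter course does not fit the requested grid")
    centerline = BinaryMask(_rasterize_polyline(path, shape), spacing)
    gt_mask = dilate_disk(centerline, stroke_radius)
    _, n_gt = label_components(gt_mask)
    if n_gt != 1:
        raise GeometryError("ground-truth curve is not a single component")
    true_tip = extract_tip(gt_mask)
    if true_tip.row <= 0.27 * rows:
        raise GeometryError("catheter tip is not inferior to the trachea")

    # degraded prediction: fragmented curve + distractors
    pred = fragment_mask(
        gt_mask,
        params.n_gaps,
        params.gap_len_px_range,
        seed=int(rng.integers(0, 2**31 - 1)),
        protect_tip=params.protect_tip,
    ).values.copy()

    offset_px = params.distractor_offset_mm / min(spacing)
    dist_to_gt = ndimage.distance_transform_edt(~gt_mask.values, sampling=spacing)
    max_gt_col = np.nonzero(gt_mask.values)[1].max()
    for k in range(params.n_distractors):
        placed = False
        base = max_gt_col + offset_px + 25 * k + 15
        for _ in range(8):  # shift laterally until the offset guarantee holds
            if base + 12 >= cols:
                break
            cand = _rasterize_polyline(
                _distractor_path(shape, base, float(true_tip.row), rng), shape
            )
            cand = dilate_disk(BinaryMask(cand, spacing), stroke_radius).values
            if dist_to_gt[cand].min() >= params.distractor_offset_mm:
                pred |= cand
                placed = True
                break
            base += 10
        if not placed:
            raise GeometryError(
                f"cannot place distractor {k} at offset {params.distractor_offset_mm} mm"
            )

    prediction = BinaryMask(pred, spacing)
    image = _render_image(gt_mask, trachea_mask, prediction, rng) if params.render_image else None
    return PhantomSample(gt_mask, prediction, trachea_mask, true_tip, params, image)


def _render_image(
    gt: BinaryMask, trachea: BinaryMask, pred: BinaryMask, rng: np.random.Generator
) -> RasterGrid:
    """Decorative grayscale rendering (soft gradient + line attenuation)."""
    rows, cols = gt.shape
    yy = np.linspace(0, 1, rows)[:, None]
    base = 110 + 40 * yy + 5 * rng.normal(size=(rows, cols))
    base[trachea.values] -= 25
    base[gt.values | pred.values] += 45
    return RasterGrid(np.clip(base, 0, 255).astype(np.uint8), gt.spacing_mm)


def fragment_mask(
    mask: BinaryMask,
    n_gaps: int,
    gap_len_px_range: tuple[int, int],
    seed: int,
    protect_tip: bool = True,
) -> BinaryMask:
    """Cut ``n_gaps`` disjoint gaps out of a single curvilinear component.

    The curve is parametrized by geodesic distance along its skeleton from
    the superior endpoint; each gap removes the mask pixels whose nearest
    skeleton pixel falls in a run of skeleton positions, cutting the stroke
    perpendicular to the course. The first 5% of the curve is never cut, nor
    is the last 5% while ``protect_tip`` holds, so the tip fragment survives.
    """
    if n_gaps == 0:
        return mask.with_values(mask.values.copy())
    _, n_in = label_components(mask)
    if n_in != 1:
        raise GeometryError("fragment_mask expects a single-component curve")
    rng = np.random.default_rng(seed)
    skel = skeletonize(mask)
    sup, _ = skeleton_endpoints(skel)
    hops = _geodesic_hops(skel.values, (int(sup.row), int(sup.col)))
    n_pos = max(hops.values()) + 1
    lo_prot = int(np.floor(0.05 * n_pos))
    hi_prot = n_pos - int(np.floor(0.05 * n_pos)) if protect_tip else n_pos

    hop_map = np.full(mask.shape, -1, dtype=int)
    for (r, c), h in hops.items():
        hop_map[r, c] = h
    # nearest-skeleton-pixel parametrization of every mask pixel
    _, (ir, ic) = ndimage.distance_transform_edt(~skel.values, return_indices=True)
    pixel_pos = hop_map[ir, ic]

    width = max(3, 2 * int(np.ceil((np.count_nonzero(mask.values) / n_pos))))
    min_sep = max(6, width)
    for _attempt in range(25):
        intervals = _draw_gap_intervals(
            rng, n_gaps, gap_len_px_range, lo_prot, hi_prot, min_sep
        )
        if intervals is None:
            raise GeometryError(
                f"curve of {n_pos} px cannot host {n_gaps} gaps of {gap_len_px_range}"
            )
        cut = np.zeros(mask.shape, dtype=bool)
        for a, b in intervals:
            cut |= mask.values & (pixel_pos >= a) & (pixel_pos < b)
        out = mask.with_values(mask.values & ~cut)
        _, n_out = label_components(out)
        if n_out == n_gaps + 1:
            return out
    raise GeometryError("failed to cut the requested number of gaps cleanly")


def _draw_gap_intervals(
    rng: np.random.Generator,
    n_gaps: int,
    len_range: tuple[int, int],
    lo: int,
    hi: int,
    min_sep: int,
) -> list[tuple[int, int]] | None:
    lo_len, hi_len = len_range
    if hi - lo < n_gaps * (hi_len + min_sep):
        return None
    for _ in range(200):
        lens = rng.integers(lo_len, hi_len + 1, size=n_gaps)
        starts = rng.integers(lo, hi - lens, size=n_gaps)
        ivs = sorted(zip(starts.tolist(), (starts + lens).tolist()))
        if all(b + min_sep <= a2 for (_, b), (a2, _) in zip(ivs[:-1], ivs[1:])):
            return [(int(a), int(b)) for a, b in ivs]
    return None


# ---------------------------------------------------------------------------
# Phantom sets on disk
# ---------------------------------------------------------------------------

def write_phantom_set(n: int, params: PhantomParams, out_dir: str | Path) -> dict:
    """Write ``n`` phantom samples (PNG masks) plus a JSON manifest.

    Per-sample seeds are derived as ``params.seed + index`` so any sample can
    be regenerated bit-exactly from the manifest alone.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    samples = []
    for i in range(n):
        p = PhantomParams(**{**asdict(params), "seed": params.seed + i})
        p.shape_px = tuple(p.shape_px)
        p.spacing_mm = tuple(p.spacing_mm)
        p.gap_len_px_range = tuple(p.gap_len_px_range)
        sample = generate_phantom(p)
        sid = f"phantom_{i:04d}"
        files = {
            "gt": f"{sid}_gt.png",
            "pred": f"{sid}_pred.png",
            "trachea": f"{sid}_trachea.png",
        }
        write_mask(sample.gt_mask, out_dir / files["gt"])
        write_mask(sample.prediction, out_dir / files["pred"])
        write_mask(sample.trachea_mask, out_dir / files["trachea"])
        if sample.image is not None:
            files["image"] = f"{sid}_image.png"
            from imageio.v3 import imwrite

            imwrite(out_dir / files["image"], sample.image.values)
        samples.append(
            {
                "id": sid,
                "seed": p.seed,
                "files": files,
                "true_tip": [int(sample.true_tip.row), int(sample.true_tip.col)],
                "spacing_mm": list(p.spacing_mm),
            }
        )
    manifest = {"samples": samples, "params": _params_json(params)}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _params_json(params: PhantomParams) -> dict:
    d = asdict(params)
    for key in ("shape_px", "spacing_mm", "gap_len_px_range"):
        d[key] = list(d[key])
    return d


def load_phantom_set(manifest_path: str | Path) -> list[dict]:
    """Reload a written phantom set; each entry carries the loaded masks."""
    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    out = []
    for s in manifest["samples"]:
        spacing = tuple(s["spacing_mm"])
        entry = dict(s)
        entry["gt_mask"] = read_mask(manifest_path.parent / s["files"]["gt"], spacing)
        entry["prediction"] = read_mask(manifest_path.parent / s["files"]["pred"], spacing)
        entry["trachea_mask"] = read_mask(
            manifest_path.parent / s["files"]["trachea"], spacing
        )
        entry["true_tip"] = PointRC(*s["true_tip"])
        out.append(entry)
    return out
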