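"""Bidirectional Connect: reconnect fragmented line predictions.

CNN predictions of thin catheters frequently come out as several line
fragments plus the occasional distractor blob. Bidirectional Connect anchors
on the largest connected component, skeletonizes it, and from each of its
two endpoints (superior and inferior) marches outward along the local
tangent, sweeping a forward half-disk at every step. Any fragment the sweep
touches is absorbed whole, bridged to the curve by a digital straight
segment, and the march continues from the fragment's far endpoint with a
re-estimated direction. The search from one endpoint stops once the
cumulative empty-space travel exceeds a budget or the image edge is reached.
The union of skeletons and bridges is finally dilated back to a consistent
stroke width, yielding one smooth continuous curve.

Distances and radii are physical (mm, via the mask's pixel spacing);
directions are unit vectors in (row, col) index space.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.draw import line as bresenham_line

from .errors import DirectionUndefinedError, EmptyMaskError, ParameterError
from .raster import (
    BinaryMask,
    PointRC,
    dilate_disk,
    label_components,
    largest_component,
    skeletonize,
)

__all__ = [
    "BDConnectParams",
    "TracePath",
    "ConnectResult",
    "skeleton_endpoints",
    "outward_direction",
    "semicircle_scan",
    "interpolate_gap",
    "estimate_stroke_radius",
    "bidirectional_connect",
    "connect_with_trace",
]


@dataclass
class BDConnectParams:
    """Tunable geometry of the marching half-disk search.

    scan_radius_mm
        Radius of the forward half-disk swept at each step.
    step_fraction
        March step as a fraction of the scan radius (in (0, 1]).
    max_gap_mm
        Per-endpoint budget of empty-space travel (steps + bridged gaps).
    direction_lookback_px
        Geodesic distance along the skeleton used to estimate the outward
        tangent at an endpoint; larger values smooth direction quantization.
    dilation_radius_px
        Final stroke radius; ``None`` means half the anchor's median stroke
        width (at least 1 px), estimated from the distance transform.
    angle_half_aperture_deg
        Half-aperture of the sweep around the march direction; 90 degrees
        is the full forward half-disk.
    """

    scan_radius_mm: float = 10.0
    step_fraction: float = 0.5
    max_gap_mm: float = 40.0
    direction_lookback_px: int = 10
    dilation_radius_px: float | None = None
    angle_half_aperture_deg: float = 90.0

    def __post_init__(self) -> None:
        if self.scan_radius_mm <= 0 or self.max_gap_mm <= 0:
            raise ParameterError("scan radius and gap budget must be positive")
        if not 0 < self.step_fraction <= 1:
            raise ParameterError("step_fraction must lie in (0, 1]")
        if self.direction_lookback_px < 1:
            raise ParameterError("direction_lookback_px must be >= 1")
        if self.dilation_radius_px is not None and self.dilation_radius_px < 0:
            raise ParameterError("dilation_radius_px must be >= 0")
        if not 0 < self.angle_half_aperture_deg <= 90:
            raise ParameterError("angle_half_aperture_deg must lie in (0, 90]")


@dataclass
class TracePath:
    """An ordered 8-connected pixel path plus the ROIs it absorbed."""

    points: list[PointRC] = field(default_factory=list)
    source_components: list[int] = field(default_factory=list)


@dataclass
class ConnectResult:
    """Full output of a Bidirectional Connect run, for inspection/plotting."""

    output: BinaryMask
    anchor: BinaryMask
    absorbed_labels: list[int]
    bridges: list[TracePath]
    dilation_radius_px: float


def skeleton_endpoints(skeleton: BinaryMask) -> tuple[PointRC, PointRC]:
    """Superior (min-row) and inferior (max-row) skeleton pixels.

    Row ties are broken by the smaller column. A single-pixel skeleton
    returns that pixel twice.
    """
    if skeleton.is_empty:
        raise EmptyMaskError("skeleton_endpoints of an empty skeleton")
    rows, cols = np.nonzero(skeleton.values)
    order = np.lexsort((cols, rows))
    sup = PointRC(int(rows[order[0]]), int(cols[order[0]]))
    max_row = rows.max()
    at_max = cols[rows == max_row]
    inf = PointRC(int(max_row), int(at_max.min()))
    return sup, inf


def _geodesic_hops(skeleton: np.ndarray, start: tuple[int, int]) -> dict[tuple[int, int], int]:
    """BFS hop count along the skeleton's 8-neighborhood from ``start``."""
    dist = {start: 0}
    queue = deque([start])
    rows, cols = skeleton.shape
    while queue:
        r, c = queue.popleft()
        d = dist[(r, c)]
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                rr, cc = r + dr, c + dc
                if 0 <= rr < rows and 0 <= cc < cols and skeleton[rr, cc]:
                    if (rr, cc) not in dist:
                        dist[(rr, cc)] = d + 1
                        queue.append((rr, cc))
    return dist


def outward_direction(
    endpoint: PointRC, skeleton: BinaryMask, lookback_px: int = 10
) -> tuple[float, float]:
    """Unit tangent at a skeleton endpoint, pointing away from the curve body.

    The reference point is the skeleton pixel at geodesic (along-skeleton)
    hop distance ``min(lookback_px, path length)`` from the endpoint; using a
    lookback rather than the immediate neighbor avoids quantizing the
    direction to multiples of 45 degrees.
    """
    ep = (int(endpoint.row), int(endpoint.col))
    if not skeleton.values[ep]:
        raise ParameterError(f"endpoint {endpoint} is not on the skeleton")
    hops = _geodesic_hops(skeleton.values, ep)
    target = min(lookback_px, max(hops.values()))
    if target == 0:
        raise DirectionUndefinedError("single-pixel skeleton has no tangent")
    at_target = sorted(p for p, d in hops.items() if d == target)
    q = at_target[0]
    v = np.array([ep[0] - q[0], ep[1] - q[1]], dtype=float)
    v /= np.linalg.norm(v)
    return (float(v[0]), float(v[1]))


def semicircle_scan(
    current: PointRC,
    direction: tuple[float, float],
    candidates: BinaryMask,
    params: BDConnectParams | None = None,
) -> PointRC | None:
    """Sweep the forward half-disk at ``current`` and pick the best candidate.

    Candidate pixels within ``scan_radius_mm`` (physical distance) and within
    the angular aperture of ``direction`` are ranked by angular deviation,
    then distance, then (row, col); ``None`` when the half-disk is empty.
    """
    params = params or BDConnectParams()
    rows, cols = np.nonzero(candidates.values)
    if rows.size == 0:
        return None
    return _scan_coords(
        np.asarray(current, dtype=float),
        np.asarray(direction, dtype=float),
        rows,
        cols,
        candidates.spacing_mm,
        params,
    )


def _scan_coords(
    current: np.ndarray,
    direction: np.ndarray,
    rows: np.ndarray,
    cols: np.ndarray,
    spacing: tuple[float, float],
    params: BDConnectParams,
) -> PointRC | None:
    dr = rows - current[0]
    dc = cols - current[1]
    dist_mm = np.hypot(dr * spacing[0], dc * spacing[1])
    norm = np.hypot(dr, dc)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = (dr * direction[0] + dc * direction[1]) / norm
    angle = np.arccos(np.clip(cosang, -1.0, 1.0))
    keep = (
        (dist_mm > 1e-12)
        & (dist_mm <= params.scan_radius_mm)
        & (angle <= np.deg2rad(params.angle_half_aperture_deg) + 1e-12)
    )
    if not keep.any():
        return None
    idx = np.flatnonzero(keep)
    best = idx[np.lexsort((cols[idx], rows[idx], dist_mm[idx], angle[idx]))[0]]
    return PointRC(int(rows[best]), int(cols[best]))


def interpolate_gap(p1: PointRC, p2: PointRC) -> list[PointRC]:
    """8-connected digital straight segment from p1 to p2 inclusive."""
    r0, c0 = int(p1.row), int(p1.col)
    r1, c1 = int(p2.row), int(p2.col)
    if (r0, c0) == (r1, c1):
        return [PointRC(r0, c0)]
    rr, cc = bresenham_line(r0, c0, r1, c1)
    return [PointRC(int(r), int(c)) for r, c in zip(rr, cc)]


def estimate_stroke_radius(mask: BinaryMask) -> float:
    """Half the median stroke width of a line-like mask, at least 1 px.

    The median stroke width is taken as twice the mean distance-to-background
    over foreground pixels.
    """
    if mask.is_empty:
        raise EmptyMaskError("cannot estimate stroke width of an empty mask")
    dist = ndimage.distance_transform_edt(mask.values)
    return float(max(1.0, dist[mask.values].mean()))


def bidirectional_connect(
    prediction: BinaryMask,
    params: BDConnectParams | None = None,
    search_endpoints: str = "both",
) -> BinaryMask:
    """Reconnect a fragmented line prediction into one continuous curve."""
    return connect_with_trace(prediction, params, search_endpoints).output


def connect_with_trace(
    prediction: BinaryMask,
    params: BDConnectParams | None = None,
    search_endpoints: str = "both",
) -> ConnectResult:
    """As :func:`bidirectional_connect`, returning the full trace."""
    params = params or BDConnectParams()
    if search_endpoints not in ("both", "superior", "inferior"):
        raise ParameterError(f"unknown endpoint selection {search_endpoints!r}")
    if prediction.is_empty:
        raise EmptyMaskError("bidirectional_connect of an empty prediction")

    anchor = largest_component(prediction)
    radius = (
        params.dilation_radius_px
        if params.dilation_radius_px is not None
        else estimate_stroke_radius(anchor)
    )
    if anchor.count == 1:
        warnings.warn("single-pixel anchor: direction undefined, returning dilated anchor")
        return ConnectResult(dilate_disk(anchor, radius), anchor, [], [], radius)

    labels, _ = label_components(prediction)
    anchor_seed = tuple(np.argwhere(anchor.values)[0])
    anchor_label = int(labels[anchor_seed])

    anchor_skel = skeletonize(anchor)
    curve = anchor_skel.values.copy()
    absorbed: set[int] = {anchor_label}
    bridges: list[TracePath] = []

    # per-label skeletons are computed lazily as fragments get absorbed
    spacing = prediction.spacing_mm
    shape = prediction.shape
    all_r, all_c = np.nonzero(prediction.values)
    all_lab = labels[all_r, all_c]

    try:
        sup, inf = skeleton_endpoints(anchor_skel)
    except EmptyMaskError:  # pragma: no cover - anchor has >1 px, skeleton nonempty
        raise
    starts = {"both": [sup, inf], "superior": [sup], "inferior": [inf]}[search_endpoints]

    for endpoint in starts:
        _march_from(
            endpoint,
            anchor_skel,
            curve,
            labels,
            all_r,
            all_c,
            all_lab,
            absorbed,
            bridges,
            spacing,
            shape,
            params,
        )

    out_values = curve
    union = BinaryMask(out_values, spacing, prediction.connectivity)
    output = dilate_disk(union, radius)
    absorbed_rois = sorted(absorbed - {anchor_label})
    return ConnectResult(output, anchor, absorbed_rois, bridges, radius)


def _march_from(
    endpoint: PointRC,
    start_skel: BinaryMask,
    curve: np.ndarray,
    labels: np.ndarray,
    all_r: np.ndarray,
    all_c: np.ndarray,
    all_lab: np.ndarray,
    absorbed: set[int],
    bridges: list[TracePath],
    spacing: tuple[float, float],
    shape: tuple[int, int],
    params: BDConnectParams,
) -> None:
    """March outward from one endpoint, absorbing every fragment hit."""
    try:
        direction = np.asarray(
            outward_direction(endpoint, start_skel, params.direction_lookback_px)
        )
    except DirectionUndefinedError:
        return
    pos = np.asarray(endpoint, dtype=float)
    bridged_mm = 0.0  # empty space actually crossed by bridges so far
    march_mm = 0.0  # marching since the last absorption (superseded by its bridge)
    step_mm = params.step_fraction * params.scan_radius_mm

    while bridged_mm + march_mm <= params.max_gap_mm:
        active = ~np.isin(all_lab, list(absorbed))
        hit = None
        if active.any():
            hit = _scan_coords(
                pos, direction, all_r[active], all_c[active], spacing, params
            )
        if hit is None:
            # advance one physical step along the tangent through empty space
            phys_norm = np.hypot(direction[0] * spacing[0], direction[1] * spacing[1])
            pos = pos + step_mm * direction / phys_norm
            march_mm += step_mm
            if not (0 <= pos[0] < shape[0] and 0 <= pos[1] < shape[1]):
                return
            continue

        lab = int(labels[int(hit.row), int(hit.col)])
        comp = BinaryMask(labels == lab, spacing)
        comp_skel = skeletonize(comp)

        # bridge: nearest pixel of the evolving curve -> nearest skeleton
        # pixel of the absorbed fragment (avoids doubling back)
        src = _nearest_pixel(curve, hit, spacing)
        tgt = _nearest_pixel(comp_skel.values, src, spacing)
        path = interpolate_gap(src, tgt)
        for p in path:
            curve[int(p.row), int(p.col)] = True
        curve |= comp_skel.values
        absorbed.add(lab)
        bridges.append(TracePath(points=path, source_components=[lab]))
        # the bridge spans the same empty space just marched, so it replaces
        # the marching distance in the budget rather than adding to it
        bridged_mm += float(
            np.hypot((src.row - tgt.row) * spacing[0], (src.col - tgt.col) * spacing[1])
        )
        march_mm = 0.0

        # continue from the fragment's far endpoint (most distal in the
        # current walk direction) with a re-estimated tangent
        e1, e2 = skeleton_endpoints(comp_skel)
        far = max(
            (e1, e2),
            key=lambda e: (e.row - pos[0]) * direction[0] + (e.col - pos[1]) * direction[1],
        )
        try:
            direction = np.asarray(
                outward_direction(far, comp_skel, params.direction_lookback_px)
            )
        except DirectionUndefinedError:
            return
        pos = np.asarray(far, dtype=float)


def _nearest_pixel(values: np.ndarray, to: PointRC, spacing: tuple[float, float]) -> PointRC:
    rows, cols = np.nonzero(values)
    d = np.hypot((rows - to.row) * spacing[0], (cols - to.col) * spacing[1])
    i = np.lexsort((cols, rows, d))[0]
    return PointRC(int(rows[i]), int(cols[i]))
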