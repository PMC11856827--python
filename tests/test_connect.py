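import numpy as np
import pytest
from hypothesis import given, strategies as st

from cxrline import (
    BDConnectParams,
    BinaryMask,
    EmptyMaskError,
    PointRC,
    bidirectional_connect,
    connect_with_trace,
    connected_components,
    dilate_disk,
    interpolate_gap,
    outward_direction,
    semicircle_scan,
    skeleton_endpoints,
    skeletonize,
)
from cxrline.connect import estimate_stroke_radius


def mask_from(coords, shape=(40, 40), spacing=(1.0, 1.0)):
    values = np.zeros(shape, dtype=bool)
    for r, c in coords:
        values[r, c] = True
    return BinaryMask(values, spacing)


class TestEndpoints:
    def test_vertical_line(self):
        skel = mask_from([(r, 3) for r in range(5, 21)])
        assert skeleton_endpoints(skel) == ((5, 3), (20, 3))

    def test_single_pixel_degenerate(self):
        sup, inf = skeleton_endpoints(mask_from([(7, 7)]))
        assert sup == inf == (7, 7)

    def test_c_shape_matches_row_extremum_scan(self):
        # C-shaped open curve: extremes found by brute-force row scan
        coords = (
            [(5, c) for c in range(10, 20)]
            + [(r, 10) for r in range(5, 15)]
            + [(15, c) for c in range(10, 20)]
        )
        skel = mask_from(coords)
        rows = [r for r, _ in coords]
        sup_row, inf_row = min(rows), max(rows)
        sup, inf = skeleton_endpoints(skel)
        assert sup.row == sup_row and inf.row == inf_row
        assert sup.col == min(c for r, c in coords if r == sup_row)
        assert inf.col == min(c for r, c in coords if r == inf_row)

    def test_empty_raises(self):
        with pytest.raises(EmptyMaskError):
            skeleton_endpoints(mask_from([]))


class TestOutwardDirection:
    def test_vertical_line_points_inferiorly(self):
        skel = mask_from([(r, 3) for r in range(5, 21)])
        d = outward_direction(PointRC(20, 3), skel, 10)
        assert d == pytest.approx((1.0, 0.0))

    def test_diagonal_line(self):
        skel = mask_from([(r, r) for r in range(5, 25)])
        d = outward_direction(PointRC(24, 24), skel, 10)
        assert d == pytest.approx((np.sqrt(2) / 2, np.sqrt(2) / 2), abs=0.05)

    def test_unit_norm_on_arc(self):
        # quarter-circle arc: direction is the chord over the geodesic lookback
        coords = sorted(
            {(int(round(30 - 30 * np.sin(t))), int(round(30 * np.cos(t))))
             for t in np.linspace(0, np.pi / 2, 120)}
        )
        skel = mask_from(coords, shape=(40, 40))
        sup, inf = skeleton_endpoints(skel)
        d = outward_direction(inf, skel, 10)
        assert np.hypot(*d) == pytest.approx(1.0, abs=1e-9)
        # at the inferior end of the arc the tangent is mostly downward
        assert d[0] > 0.7

    def test_single_pixel_undefined(self):
        from cxrline import DirectionUndefinedError

        with pytest.raises(DirectionUndefinedError):
            outward_direction(PointRC(7, 7), mask_from([(7, 7)]), 10)


class TestSemicircleScan:
    def test_empty_half_disk_returns_none(self):
        cand = mask_from([(5, 10)])  # behind the scan direction
        assert semicircle_scan(PointRC(10, 10), (1.0, 0.0), cand) is None

    def test_single_candidate_ahead(self):
        cand = mask_from([(15, 10)])
        hit = semicircle_scan(PointRC(10, 10), (1.0, 0.0), cand)
        assert hit == (15, 10)

    def test_angle_beats_distance(self):
        # A: 10 deg off-axis at distance 8; B: 60 deg off-axis at distance 4
        a = (10 + int(round(8 * np.cos(np.deg2rad(10)))),
             10 + int(round(8 * np.sin(np.deg2rad(10)))))
        b = (10 + int(round(4 * np.cos(np.deg2rad(60)))),
             10 + int(round(4 * np.sin(np.deg2rad(60)))))
        hit = semicircle_scan(PointRC(10, 10), (1.0, 0.0), mask_from([a, b]))
        assert hit == a

    def test_matches_exhaustive_half_disk_ordering(self, rng):
        params = BDConnectParams(scan_radius_mm=6.0)
        direction = np.array([np.sqrt(0.5), np.sqrt(0.5)])
        cand = BinaryMask(rng.random((30, 30)) < 0.1)
        cur = np.array([14.0, 14.0])
        hit = semicircle_scan(PointRC(14, 14), tuple(direction), cand, params)
        best = None
        for r, c in zip(*np.nonzero(cand.values)):
            v = np.array([r, c]) - cur
            dist = np.hypot(*v)
            if not 0 < dist <= 6.0:
                continue
            ang = np.arccos(np.clip(v @ direction / dist, -1, 1))
            if ang > np.pi / 2 + 1e-12:
                continue
            key = (ang, dist, r, c)
            if best is None or key < best:
                best = key
        expected = None if best is None else (best[2], best[3])
        assert hit == expected

    def test_radius_respected(self):
        cand = mask_from([(30, 10)])
        params = BDConnectParams(scan_radius_mm=10.0)
        assert semicircle_scan(PointRC(10, 10), (1.0, 0.0), cand, params) is None


class TestInterpolateGap:
    def test_axis_aligned(self):
        pts = interpolate_gap(PointRC(0, 0), PointRC(0, 5))
        assert pts == [(0, c) for c in range(6)]

    def test_diagonal(self):
        pts = interpolate_gap(PointRC(0, 0), PointRC(3, 3))
        assert pts == [(i, i) for i in range(4)]

    def test_identical_points(self):
        assert interpolate_gap(PointRC(4, 4), PointRC(4, 4)) == [(4, 4)]

    @given(
        st.integers(-20, 20), st.integers(-20, 20),
        st.integers(-20, 20), st.integers(-20, 20),
    )
    def test_digital_segment_properties(self, r0, c0, r1, c1):
        pts = interpolate_gap(PointRC(r0, c0), PointRC(r1, c1))
        assert pts[0] == (r0, c0) and pts[-1] == (r1, c1)
        if (r0, c0) != (r1, c1):
            assert len(pts) == max(abs(r1 - r0), abs(c1 - c0)) + 1
        for p, q in zip(pts[:-1], pts[1:]):
            assert max(abs(p.row - q.row), abs(p.col - q.col)) == 1  # 8-adjacent


def fragmented_line(gaps=((18, 24), (32, 40)), length=60, col=20, shape=(70, 45)):
    """A vertical 3-px-wide line with gaps cut out, plus component bookkeeping."""
    rows = [r for r in range(5, 5 + length) if not any(a <= r < b for a, b in gaps)]
    coords = [(r, col + dc) for r in rows for dc in (-1, 0, 1)]
    return mask_from(coords, shape=shape)


class TestBidirectionalConnect:
    def test_continuous_curve_passes_through(self):
        line = fragmented_line(gaps=())
        out = bidirectional_connect(line)
        assert len(connected_components(out)) == 1
        skel_in = skeletonize(line)
        assert not (skel_in.values & ~out.values).any()

    def test_three_fragments_reconnected(self):
        frag = fragmented_line()
        assert len(connected_components(frag)) == 3
        out = bidirectional_connect(frag)
        assert len(connected_components(out)) == 1
        for comp in connected_components(frag):
            skel = skeletonize(comp)
            assert not (skel.values & ~out.values).any()

    def test_far_blob_excluded(self):
        # distractor beyond the search envelope (40 mm budget + 10 mm radius)
        frag = fragmented_line(shape=(120, 120))
        blob = np.zeros((120, 120), dtype=bool)
        blob[8:14, 95:101] = True  # > 70 mm lateral to the line trajectory
        pred = frag.with_values(frag.values | blob)
        out = bidirectional_connect(pred)
        assert not (out.values & blob).any()
        assert len(connected_components(out)) == 1

    def test_absorbed_labels_reported(self):
        res = connect_with_trace(fragmented_line())
        assert len(res.absorbed_labels) == 2
        assert len(res.bridges) == 2

    def test_single_pixel_anchor_warns_and_dilates(self):
        mask = mask_from([(5, 5)])
        with pytest.warns(UserWarning):
            out = bidirectional_connect(mask, BDConnectParams(dilation_radius_px=1))
        assert out.values[5, 5] and out.count == 5

    def test_empty_prediction_raises(self):
        with pytest.raises(EmptyMaskError):
            bidirectional_connect(mask_from([]))

    def test_deterministic(self):
        frag = fragmented_line()
        assert bidirectional_connect(frag) == bidirectional_connect(frag)

    def test_locality_no_spontaneous_foreground(self):
        frag = fragmented_line()
        res = connect_with_trace(frag)
        skel_union = np.zeros(frag.shape, dtype=bool)
        for comp in connected_components(frag):
            skel_union |= skeletonize(comp).values
        for path in res.bridges:
            for p in path.points:
                skel_union[int(p.row), int(p.col)] = True
        envelope = dilate_disk(frag.with_values(skel_union), res.dilation_radius_px)
        assert not (res.output.values & ~envelope.values).any()

    def test_inferior_only_search(self):
        frag = fragmented_line(gaps=((18, 24),))  # one gap above the anchor?
        # anchor is the larger (lower) fragment; superior-only search must
        # absorb the upper fragment, inferior-only must not
        sup_only = connect_with_trace(frag, search_endpoints="superior")
        inf_only = connect_with_trace(frag, search_endpoints="inferior")
        assert len(sup_only.absorbed_labels) + len(inf_only.absorbed_labels) == 1

    def test_stroke_radius_estimate(self):
        line = fragmented_line(gaps=())
        r = estimate_stroke_radius(line)
        assert 1.0 <= r <= 2.0  # 3-px stroke: half-width about 1.2 px
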