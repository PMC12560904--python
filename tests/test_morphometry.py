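"""Convex hull, centroid chords, skeleton angle, perimeter and curvature."""

import numpy as np
import pytest

from pigmorph import (
    DegenerateSkeletonError,
    axes_through_centroid,
    convex_hull,
    max_contour_curvature,
    perimeter,
    skeleton_curve_angle,
    trace_contour,
)

from conftest import shape


def hull_pixel_oracle(vertices, grid_shape):
    """Count pixel centers inside (or on) the hull polygon — brute force."""
    from shapely.geometry import Point, Polygon

    poly = Polygon(vertices).buffer(1e-9)
    h, w = grid_shape
    return sum(
        poly.contains(Point(x, y)) for y in range(h) for x in range(w)
    )


class TestConvexHull:
    def test_rectangle_hull_matches_pixel_count(self):
        m = shape("rectangle", w=20, h=10, canvas=(60, 60))
        res = convex_hull(trace_contour(m), m.area)
        assert m.area == 200
        assert res.area_px2 == pytest.approx(200, rel=0.02)
        assert res.ratio < 0.02

    def test_l_shape_matches_point_in_polygon_oracle(self):
        m = shape("l_shape", long=30, thick=10, canvas=(64, 64))
        res = convex_hull(trace_contour(m), m.area)
        oracle = hull_pixel_oracle(res.vertices, m.grid.shape)
        assert res.area_px2 == pytest.approx(oracle, rel=0.02)
        assert res.difference_px2 > 0  # concave shape

    def test_bent_capsule_more_concave_than_straight(self):
        straight = shape("capsule", length=200, width=40)
        bent = shape("bent_capsule", length=200, width=40, bend_deg=120)
        r_s = convex_hull(trace_contour(straight), straight.area)
        r_b = convex_hull(trace_contour(bent), bent.area)
        assert r_b.ratio > r_s.ratio

    def test_hull_polygon_is_convex(self):
        m = shape("bent_capsule", length=150, width=30, bend_deg=100)
        v = convex_hull(trace_contour(m), m.area).vertices
        e = np.diff(np.vstack([v, v[:2]]), axis=0)
        cross = e[:-1, 0] * e[1:, 1] - e[:-1, 1] * e[1:, 0]
        assert (cross >= 0).all() or (cross <= 0).all()

    @pytest.mark.parametrize("kind,params", [
        ("disc", {"R": 40}),
        ("ellipse", {"a": 55, "b": 20}),
        ("l_shape", {"long": 40, "thick": 12}),
        ("bent_capsule", {"length": 180, "width": 36, "bend_deg": 110}),
    ])
    def test_difference_nonnegative(self, kind, params):
        m = shape(kind, **params)
        res = convex_hull(trace_contour(m), m.area)
        assert res.difference_px2 >= 0
        assert res.area_px2 >= m.area - 0.5 * perimeter(trace_contour(m))


def brute_chord_scan(grid, step_deg=0.1, step_px=0.05):
    """Independent fine-grained chord scan oracle."""
    ys, xs = np.nonzero(grid)
    cx, cy = xs.mean(), ys.mean()
    h, w = grid.shape
    best_long, best_short = -np.inf, np.inf
    for theta in np.arange(0.0, 180.0, step_deg):
        t = np.radians(theta)
        chord = 0.0
        for sign in (1.0, -1.0):
            r = step_px
            while True:
                x = int(round(cx + sign * r * np.cos(t)))
                y = int(round(cy + sign * r * np.sin(t)))
                if not (0 <= x < w and 0 <= y < h and grid[y, x]):
                    break
                r += step_px
            chord += r - step_px
        best_long = max(best_long, chord)
        best_short = min(best_short, chord)
    return best_long, best_short


class TestAxesThroughCentroid:
    def test_disc_diameter(self):
        m = shape("disc", R=40, canvas=(120, 120))
        ax = axes_through_centroid(m)
        assert ax.longest_px == pytest.approx(80, abs=2)
        assert ax.shortest_px == pytest.approx(80, abs=2)

    def test_ellipse_axes(self):
        m = shape("ellipse", a=60, b=25, canvas=(200, 120))
        ax = axes_through_centroid(m)
        assert ax.longest_px == pytest.approx(120, abs=2)
        assert ax.shortest_px == pytest.approx(50, abs=2)
        assert ax.longest_angle_deg == pytest.approx(0, abs=2)

    def test_square_diagonal_and_side(self):
        m = shape("rectangle", w=30, h=30, canvas=(80, 80))
        ax = axes_through_centroid(m)
        assert ax.longest_px == pytest.approx(30 * np.sqrt(2), abs=1.5)
        assert ax.shortest_px == pytest.approx(30, abs=1.5)

    def test_agrees_with_fine_scan_oracle(self):
        m = shape("ellipse", a=22, b=11, rotation_deg=30, canvas=(64, 64))
        ax = axes_through_centroid(m)
        long_o, short_o = brute_chord_scan(m.grid)
        assert ax.longest_px == pytest.approx(long_o, abs=1.0)
        assert ax.shortest_px == pytest.approx(short_o, abs=1.0)


class TestSkeletonCurveAngle:
    def test_straight_capsule_is_180(self):
        s = skeleton_curve_angle(shape("capsule", length=200, width=40))
        assert s.body_curve_deg == pytest.approx(180, abs=3)

    @pytest.mark.parametrize("bend", [150, 120, 90])
    def test_bent_capsule_recovers_bend(self, bend):
        m = shape("bent_capsule", length=200, width=40, bend_deg=bend)
        s = skeleton_curve_angle(m)
        assert s.body_curve_deg == pytest.approx(bend, abs=5)

    def test_monotone_in_true_bend(self):
        angles = [
            skeleton_curve_angle(
                shape("bent_capsule", length=200, width=40, bend_deg=b)
            ).body_curve_deg
            for b in (180, 150, 120, 90)
        ]
        assert angles == sorted(angles, reverse=True)

    def test_disc_raises_degenerate(self):
        with pytest.raises(DegenerateSkeletonError):
            skeleton_curve_angle(shape("disc", R=40, canvas=(120, 120)))

    def test_endpoints_and_center_on_skeleton(self):
        s = skeleton_curve_angle(shape("bent_capsule", length=180, width=36,
                                       bend_deg=130))
        pix = {tuple(p) for p in s.pixels}
        assert set(s.endpoints) <= pix
        assert tuple(s.center) in pix


class TestPerimeter:
    def test_square_side_30(self):
        m = shape("rectangle", w=30, h=30, canvas=(80, 80))
        assert perimeter(trace_contour(m)) == pytest.approx(116, abs=4)

    def test_disc_circumference(self):
        m = shape("disc", R=50, canvas=(160, 160))
        assert perimeter(trace_contour(m)) == pytest.approx(2 * np.pi * 50, rel=0.03)

    def test_2x2_square_exact(self):
        import pigmorph

        grid = np.zeros((6, 6), np.uint8)
        grid[2:4, 2:4] = 1
        c = trace_contour(pigmorph.BinaryMask(grid))
        # 4 unit steps around 4 pixel centers; too short for smoothing
        assert perimeter(c) == pytest.approx(4.0, abs=1e-12)


class TestMaxContourCurvature:
    def test_disc_kappa_is_inverse_radius(self):
        m = shape("disc", R=50, canvas=(160, 160))
        res = max_contour_curvature(trace_contour(m))
        assert res.kappa_max == pytest.approx(1 / 50, rel=0.15)

    def test_ellipse_tip_curvature(self):
        m = shape("ellipse", a=60, b=20, canvas=(200, 120))
        res = max_contour_curvature(trace_contour(m))
        assert res.kappa_max == pytest.approx(60 / 20**2, rel=0.20)

    def test_monotone_in_inverse_radius(self):
        k100 = max_contour_curvature(
            trace_contour(shape("disc", R=100, canvas=(260, 260)))).kappa_max
        k25 = max_contour_curvature(
            trace_contour(shape("disc", R=25, canvas=(100, 100)))).kappa_max
        assert k100 < k25

    def test_kappa_max_is_max_of_kappa(self):
        res = max_contour_curvature(trace_contour(shape("ellipse", a=40, b=18,
                                                        canvas=(120, 80))))
        assert res.kappa_max == res.kappa.max()
        assert len(res.resampled_points) == 200


class TestGeometricCovariance:
    def test_rotation_robustness(self):
        a = shape("bent_capsule", length=300, width=80, bend_deg=140)
        b = shape("bent_capsule", length=300, width=80, bend_deg=140,
                  rotation_deg=30)
        ca, cb = trace_contour(a), trace_contour(b)
        assert b.area == pytest.approx(a.area, rel=0.03)
        assert perimeter(cb) == pytest.approx(perimeter(ca), rel=0.03)
        axa, axb = axes_through_centroid(a), axes_through_centroid(b)
        assert axb.longest_px == pytest.approx(axa.longest_px, rel=0.03)
        assert axb.shortest_px == pytest.approx(axa.shortest_px, rel=0.03)
        ka = max_contour_curvature(ca).kappa_max
        kb = max_contour_curvature(cb).kappa_max
        assert kb == pytest.approx(ka, rel=0.20)

    def test_scale_covariance(self):
        s = 2.0
        a = shape("ellipse", a=40, b=18, canvas=(200, 200))
        b = shape("ellipse", a=40 * s, b=18 * s, canvas=(300, 300))
        assert b.area == pytest.approx(a.area * s**2, rel=0.03)
        ca, cb = trace_contour(a), trace_contour(b)
        assert perimeter(cb) == pytest.approx(perimeter(ca) * s, rel=0.03)
        axa, axb = axes_through_centroid(a), axes_through_centroid(b)
        assert axb.longest_px == pytest.approx(axa.longest_px * s, rel=0.03)
        ka = max_contour_curvature(ca).kappa_max
        kb = max_contour_curvature(cb).kappa_max
        assert kb == pytest.approx(ka / s, rel=0.20)

    def test_bend_sensitivity_shrinks_major_axis(self):
        longs, ratios = [], []
        for bend in (180, 150, 120, 90):
            m = shape("bent_capsule", length=200, width=40, bend_deg=bend)
            longs.append(
                axes_through_centroid(m, fallback_to_nearest=True).longest_px
            )
            ratios.append(convex_hull(trace_contour(m), m.area).ratio)
        assert longs == sorted(longs, reverse=True)
        # any bent posture is more concave than the straight one
        assert all(r > ratios[0] for r in ratios[1:])
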