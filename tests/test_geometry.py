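"""Contour-stack geometry: volumes, thickness, curvature, partition, fibers."""

import numpy as np
import pytest
from scipy import integrate

from v2g import geometry as g
from v2g import synthetic
from v2g.errors import V2GError


def circle(r, n=100, center=(0.0, 0.0)):
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([center[0] + r * np.cos(th),
                            center[1] + r * np.sin(th)])


def ellipse(a, b, n=200):
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([a * np.cos(th), b * np.sin(th)])


class TestResample:
    def test_circle_radius_and_spacing(self):
        out = g.resample_contour(circle(2.0, 2000), n=100)
        r = np.hypot(out[:, 0], out[:, 1])
        assert np.allclose(r, 2.0, atol=1e-5)
        seg = np.hypot(*np.diff(np.vstack([out, out[:1]]), axis=0).T)
        assert np.allclose(seg, seg.mean(), rtol=1e-3)

    def test_idempotent_on_equal_spaced_polygon(self):
        base = circle(2.0, 100)
        out = g.resample_contour(base, n=100)
        # same vertex set up to the start-point convention
        d = np.linalg.norm(base[:, None, :] - out[None, :, :], axis=2).min(axis=1)
        assert np.max(d) < 1e-9

    def test_ellipse_perimeter_preserved(self):
        a, b = 3.0, 2.0
        out = g.resample_contour(ellipse(a, b, 400), n=100)
        per = g.contour_perimeter(out)
        per_true, _ = integrate.quad(
            lambda t: np.hypot(-a * np.sin(t), b * np.cos(t)), 0, 2 * np.pi,
            limit=200)
        assert abs(per - per_true) / per_true < 1e-3

    def test_rejects_degenerate(self):
        with pytest.raises(V2GError):
            g.resample_contour(np.zeros((10, 2)))
        with pytest.raises(ValueError):
            g.resample_contour(circle(1.0), n=4)


class TestVolumes:
    def test_cylinder(self):
        slices = [g.VentricleSlice(circle(2.0), circle(2.5), z)
                  for z in np.linspace(0.25, 4.75, 10)]
        stack = g.ContourStack(slices, spacing=0.5)
        # the 100-gon area is below pi r^2 by (2 pi / 100)^2 / 6 ~ 7e-4
        assert g.stack_volume(stack, "inner") == pytest.approx(
            np.pi * 4 * 5, rel=1e-3)

    def test_hemisphere_refinement(self):
        R, n = 3.0, 50
        dz = R / n
        zc = (np.arange(n) + 0.5) * dz
        slices = [g.VentricleSlice(circle(np.sqrt(R * R - z * z)),
                                   circle(np.sqrt(R * R - z * z) + 0.2), z)
                  for z in zc]
        stack = g.ContourStack(slices, spacing=dz)
        assert g.stack_volume(stack, "inner") == pytest.approx(
            2 / 3 * np.pi * R ** 3, rel=0.02)

    def test_cubic_scaling(self, ellipsoid_stack):
        v1 = g.stack_volume(ellipsoid_stack)
        v2 = g.stack_volume(ellipsoid_stack.transformed(scale=1.7))
        assert v2 == pytest.approx(1.7 ** 3 * v1, rel=1e-9)

    def test_rigid_motion_invariance(self, ellipsoid_stack):
        th = 0.7
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        moved = ellipsoid_stack.transformed(rotation=R,
                                            translation=(1.0, -2.0, 3.0))
        assert g.stack_volume(moved) == pytest.approx(
            g.stack_volume(ellipsoid_stack), rel=1e-9)
        assert g.wall_volume(moved) == pytest.approx(
            g.wall_volume(ellipsoid_stack), rel=1e-9)

    def test_rejects_single_slice(self):
        stack = g.ContourStack([g.VentricleSlice(circle(1), circle(1.2), 0.0)],
                               spacing=0.5)
        with pytest.raises(V2GError):
            g.stack_volume(stack)


class TestWallThickness:
    def test_concentric_circles(self):
        sl = g.VentricleSlice(circle(2.0), circle(2.5), 0.0)
        t, mean, miss = g.wall_thickness(sl)
        assert np.allclose(t, 0.5, atol=1e-6)
        assert mean == pytest.approx(0.5, abs=1e-6)
        assert not miss.any()

    def test_similar_ellipses_vs_brute_force(self):
        sl = g.VentricleSlice(ellipse(3.0, 2.0), ellipse(3.45, 2.3), 0.0)
        t, _, _ = g.wall_thickness(sl)
        rs = sl.resampled()
        dense = g.resample_contour(sl.outer, 100)
        # dense nearest-distance brute force (lower bound on ray distance)
        from shapely.geometry import LinearRing, Point
        ring = LinearRing(np.vstack([dense, dense[:1]]))
        nearest = np.array([ring.distance(Point(p)) for p in rs.inner])
        assert np.all(t >= nearest - 1e-9)
        # for mildly eccentric walls the two notions stay within a few percent
        assert np.median(np.abs(t - nearest) / nearest) < 0.05

    def test_rotation_invariance(self):
        sl = g.VentricleSlice(ellipse(3.0, 2.0), ellipse(3.4, 2.4), 0.0)
        th = 1.1
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        sl_rot = g.VentricleSlice(sl.inner @ R.T, sl.outer @ R.T, 0.0)
        _, m1, _ = g.wall_thickness(sl)
        _, m2, _ = g.wall_thickness(sl_rot)
        assert m2 == pytest.approx(m1, rel=1e-6)


class TestCurvature:
    def test_circle(self):
        k, mean = g.circumferential_curvature(circle(2.0))
        assert np.allclose(k, 0.5, rtol=1e-6)
        assert mean == pytest.approx(0.5, rel=1e-6)

    def test_collinear_window_zero(self):
        pts = np.column_stack([np.linspace(0, 1, 9), np.zeros(9)])
        assert g._circle_fit_curvature(pts) == 0.0

    def test_ellipse_vs_analytic(self):
        a, b = 3.0, 2.0
        pts = g.resample_contour(ellipse(a, b, 600), n=100)
        k, _ = g.circumferential_curvature(pts)
        t = np.arctan2(pts[:, 1] / b, pts[:, 0] / a)
        k_true = a * b / (a ** 2 * np.sin(t) ** 2
                          + b ** 2 * np.cos(t) ** 2) ** 1.5
        assert np.max(np.abs(k - k_true) / k_true) < 0.02

    def test_sphere_longitudinal(self, sphere_stack):
        k, _ = g.longitudinal_curvature(sphere_stack)
        interior = k[5:-5, :]
        assert np.max(np.abs(interior - 1.0 / 3.0) * 3.0) < 0.02

    def test_cylinder_longitudinal_zero(self):
        slices = [g.VentricleSlice(circle(2.0), circle(2.4), z)
                  for z in np.linspace(0, 4, 9)]
        stack = g.ContourStack(slices, spacing=0.5)
        k, mean = g.longitudinal_curvature(stack)
        assert mean == pytest.approx(0.0, abs=1e-8)

    def test_translation_invariance_along_z(self, sphere_stack):
        moved = sphere_stack.transformed(translation=(0, 0, 5.0))
        _, m1 = g.longitudinal_curvature(sphere_stack)
        _, m2 = g.longitudinal_curvature(moved)
        assert m2 == pytest.approx(m1, rel=1e-9)

    def test_inverse_scaling(self, sphere_stack):
        _, m1 = g.longitudinal_curvature(sphere_stack)
        _, m2 = g.longitudinal_curvature(sphere_stack.transformed(scale=2.0))
        assert m2 == pytest.approx(m1 / 2.0, rel=1e-6)


class TestQuarterPartition:
    def test_circle_equal_quarters(self):
        sl = g.VentricleSlice(circle(2.0), circle(2.5), 0.0)
        quarters = g.quarter_partition(sl)
        assert [len(q) for q in quarters] == [25, 25, 25, 25]

    def test_disjoint_cover_and_arc_conservation(self):
        sl = g.VentricleSlice(ellipse(4.0, 1.5), ellipse(4.4, 1.9), 0.0)
        quarters = g.quarter_partition(sl)
        all_idx = np.concatenate(quarters)
        assert sorted(all_idx) == list(range(100))
        inner = g.resample_contour(sl.inner, 100)
        closed = np.vstack([inner, inner[:1]])
        seg = np.hypot(*np.diff(closed, axis=0).T)
        L = seg.sum()
        # each quarter's arc length within half a point-spacing of L/4
        for q in quarters:
            arc = seg[q].sum()
            assert abs(arc - L / 4) <= 0.75 * L / 100

    def test_matches_cumulative_arc_search(self):
        sl = g.VentricleSlice(ellipse(5.0, 1.2), ellipse(5.4, 1.6), 0.0)
        quarters = g.quarter_partition(sl)
        inner = g.resample_contour(sl.inner, 100)
        closed = np.vstack([inner, inner[:1]])
        cum = np.concatenate([[0], np.cumsum(np.hypot(
            *np.diff(closed, axis=0).T))])
        L = cum[-1]
        for k in range(1, 4):
            boundary = quarters[k][0]
            assert boundary == int(np.searchsorted(cum, k * L / 4))


class TestFibers:
    def test_angle_zero_is_circumferential(self, sphere_stack):
        spec = g.FiberLayerSpec(epi_angle_deg=1e-9, endo_angle_deg=1e-9)
        f = g.assign_fibers(sphere_stack, spec)
        assert np.allclose(np.abs(f["endo"][:, :, 2]), 0.0, atol=1e-9)

    def test_angle_90_is_longitudinal(self, sphere_stack):
        spec = g.FiberLayerSpec(epi_angle_deg=90.0, endo_angle_deg=90.0)
        f = g.assign_fibers(sphere_stack, spec)
        # fiber orthogonal to the circumferential tangent everywhere
        endo = f["endo"][5:-5]
        tang = np.cross(f["transmural"][5:-5], endo)  # not needed for check
        # longitudinal direction has no circumferential component:
        # dot with in-plane tangent of the contour
        rs = sphere_stack.resampled()
        pts = np.stack([s.inner for s in rs.slices])[5:-5]
        t2 = np.roll(pts, -1, axis=1) - np.roll(pts, 1, axis=1)
        t3 = np.dstack([t2, np.zeros(t2.shape[:2])])
        t3 /= np.linalg.norm(t3, axis=2, keepdims=True)
        assert np.max(np.abs(np.sum(endo * t3, axis=2))) < 1e-9

    def test_unit_norm_and_orthogonal_to_transmural(self, ellipsoid_stack):
        f = g.assign_fibers(ellipsoid_stack)
        for layer in ("endo", "epi"):
            n = np.linalg.norm(f[layer], axis=2)
            assert np.allclose(n, 1.0, atol=1e-9)
            dots = np.sum(f[layer] * f["transmural"], axis=2)
            assert np.max(np.abs(dots)) < 1e-9

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            g.FiberLayerSpec(epi_angle_deg=120.0)
        with pytest.raises(ValueError):
            g.FiberLayerSpec(boundary_fraction=0.0)


class TestIO:
    def test_json_round_trip(self, ellipsoid_stack, tmp_path):
        path = tmp_path / "stack.json"
        ellipsoid_stack.to_json(path)
        loaded = g.ContourStack.from_json(path)
        assert g.stack_volume(loaded) == pytest.approx(
            g.stack_volume(ellipsoid_stack), rel=1e-12)
        assert len(loaded.slices) == len(ellipsoid_stack.slices)

    def test_invalid_slice_rejected(self):
        with pytest.raises(V2GError):
            g.VentricleSlice(circle(2.5), circle(2.0), 0.0)  # inner > outer

    def test_non_monotone_z_rejected(self):
        sl = [g.VentricleSlice(circle(2), circle(2.4), z) for z in (0, 1, 0.5)]
        with pytest.raises(V2GError):
            g.ContourStack(sl, spacing=0.5)
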