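"""Geometric primitives: rotations, projection, 2-D angles, cylinder fit."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from limbproj import (
    Axis3,
    DegenerateGeometryError,
    GeometryError,
    InsufficientDataError,
    angle_2d,
    fit_cylinder_axis,
    project_coronal,
    rotate_about_axis,
    signed_point_line_distance_2d,
)
from limbproj.geometry import point_axis_distance

Z_AXIS = Axis3(np.zeros(3), np.array([0.0, 0.0, 1.0]))


class TestRotateAboutAxis:
    def test_canonical_quarter_turn(self):
        out = rotate_about_axis(np.array([1.0, 0.0, 0.0]), Z_AXIS, 90.0)
        np.testing.assert_allclose(out, [0.0, 1.0, 0.0], atol=1e-12)

    def test_zero_angle_is_identity(self, rng):
        pts = rng.normal(size=(20, 3)) * 100
        out = rotate_about_axis(pts, Z_AXIS, 0.0)
        np.testing.assert_array_equal(out, pts)

    def test_composition_equals_direct(self, rng):
        """Three 10-deg turns equal one 30-deg turn (compose-vs-direct oracle)."""
        axis = Axis3(rng.normal(size=3), _unit(rng.normal(size=3)))
        pts = rng.normal(size=(100, 3)) * 200
        stepped = pts
        for _ in range(3):
            stepped = rotate_about_axis(stepped, axis, 10.0)
        direct = rotate_about_axis(pts, axis, 30.0)
        np.testing.assert_allclose(stepped, direct, atol=1e-9)

    def test_rigidity_and_axis_fixity(self, rng):
        """Pairwise distances preserved; points on the axis do not move."""
        for _ in range(10):
            axis = Axis3(rng.normal(size=3) * 50, _unit(rng.normal(size=3)))
            pts = rng.normal(size=(15, 3)) * 300
            angle = rng.uniform(-180, 180)
            out = rotate_about_axis(pts, axis, angle)
            d_in = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
            d_out = np.linalg.norm(out[:, None] - out[None], axis=-1)
            np.testing.assert_allclose(d_out, d_in, atol=1e-9)
            on_axis = axis.origin + np.outer(rng.uniform(-100, 100, 5), axis.direction)
            moved = rotate_about_axis(on_axis, axis, angle)
            np.testing.assert_allclose(moved, on_axis, atol=1e-9)

    def test_non_unit_axis_rejected(self):
        with pytest.raises(GeometryError):
            Axis3(np.zeros(3), np.array([0.0, 0.0, 2.0]))


class TestProjection:
    @pytest.mark.parametrize("p,expected", [
        ((3.0, 7.0, -2.0), (3.0, -2.0)),
        ((0.0, 0.0, 0.0), (0.0, 0.0)),
    ])
    def test_definition(self, p, expected):
        np.testing.assert_array_equal(project_coronal(np.array(p)), expected)

    def test_idempotent(self, rng):
        p = rng.normal(size=3)
        once = project_coronal(p)
        np.testing.assert_array_equal(project_coronal(once), once)

    def test_projection_commutes_with_direct_recomputation(self, rng):
        """Projecting a rotated point equals rotating, then projecting."""
        pts = rng.normal(size=(30, 3)) * 100
        rot = rotate_about_axis(pts, Z_AXIS, 37.0)
        np.testing.assert_allclose(project_coronal(rot),
                                   np.array([project_coronal(q) for q in rot]))


class TestAngle2D:
    def test_examples(self):
        assert angle_2d((0, 1), (0, 1)) == pytest.approx(0.0, abs=1e-12)
        assert angle_2d((1, 0), (0, 1)) == pytest.approx(90.0, abs=1e-12)

    def test_near_opposite_matches_atan2_oracle(self):
        u, v = np.array([1.0, 0.0]), np.array([-1.0, 1e-3])
        expected = np.degrees(np.arctan2(u[0] * v[1] - u[1] * v[0], np.dot(u, v)))
        assert angle_2d(u, v) == pytest.approx(expected, abs=1e-9)
        assert angle_2d(u, v) == pytest.approx(179.9427, abs=1e-3)

    def test_zero_vector_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            angle_2d((0.0, 0.0), (1.0, 0.0))

    @settings(max_examples=50, derandomize=True)
    @given(ux=st.floats(-10, 10), uz=st.floats(-10, 10),
           vx=st.floats(-10, 10), vz=st.floats(-10, 10),
           s=st.floats(0.01, 100), t=st.floats(0.01, 100))
    def test_symmetry_and_scale_invariance(self, ux, uz, vx, vz, s, t):
        u, v = np.array([ux, uz]), np.array([vx, vz])
        if np.linalg.norm(u) < 1e-3 or np.linalg.norm(v) < 1e-3:
            return
        assert angle_2d(u, v) == pytest.approx(angle_2d(v, u), abs=1e-9)
        assert angle_2d(s * u, t * v) == pytest.approx(angle_2d(u, v), abs=1e-7)


class TestSignedDistance:
    def test_point_on_line(self):
        assert signed_point_line_distance_2d((0.5, 0.5), (0, 0), (1, 1)) == pytest.approx(0.0, abs=1e-12)

    def test_unit_lateral_offset(self):
        # Vertical line x = 0 running proximal->distal; p one mm lateral.
        d = signed_point_line_distance_2d((1.0, 0.0), (0.0, 1.0), (0.0, -1.0), medial_sign=1.0)
        assert d == pytest.approx(1.0, abs=1e-12)

    def test_coincident_line_points_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            signed_point_line_distance_2d((1, 0), (2, 2), (2, 2))

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.floats(-100, 100), min_size=6, max_size=6))
    def test_matches_cross_product_oracle(self, vals):
        p, a, b = np.array(vals[:2]), np.array(vals[2:4]), np.array(vals[4:])
        if np.linalg.norm(b - a) < 1e-3:
            return
        d = b - a
        cross = d[0] * (p - a)[1] - d[1] * (p - a)[0]
        expected_mag = abs(cross) / np.linalg.norm(d)
        got = signed_point_line_distance_2d(p, a, b)
        assert abs(got) == pytest.approx(expected_mag, abs=1e-9)
        assert np.sign(got) == np.sign(cross) or cross == 0


def _unit(v):
    return v / np.linalg.norm(v)


def _cylinder_cloud(axis: Axis3, radius: float, n: int, rng, noise: float = 0.0):
    e1, e2 = _perp(axis.direction)
    ts = rng.uniform(-40, 40, n)
    angs = rng.uniform(0, 2 * np.pi, n)
    pts = (axis.origin + np.outer(ts, axis.direction)
           + radius * (np.outer(np.cos(angs), e1) + np.outer(np.sin(angs), e2)))
    if noise:
        pts = pts + rng.normal(0, noise, pts.shape)
    return pts


def _perp(d):
    h = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = _unit(np.cross(d, h))
    return e1, np.cross(d, e1)


class TestCylinderFit:
    def test_exact_recovery(self, rng):
        true = Axis3(np.array([3.0, -2.0, 5.0]), _unit(np.array([0.9, 0.1, 0.2])))
        pts = _cylinder_cloud(true, 22.0, 200, rng)
        start = Axis3(true.origin + rng.normal(0, 2, 3),
                      _unit(true.direction + rng.normal(0, 0.03, 3)))
        fit = fit_cylinder_axis(pts, start)
        assert _axis_angle(fit.direction, true.direction) < 1e-6
        assert np.std(point_axis_distance(pts, fit)) < 1e-8

    def test_noisy_recovery_within_half_degree(self, rng):
        true = Axis3(np.zeros(3), _unit(np.array([1.0, 0.05, -0.1])))
        pts = _cylinder_cloud(true, 22.0, 200, rng, noise=0.5)
        fit = fit_cylinder_axis(pts, Axis3(np.zeros(3), true.direction))
        assert np.degrees(_axis_angle(fit.direction, true.direction)) < 0.5

    def test_too_few_points(self, rng):
        true = Axis3(np.zeros(3), np.array([1.0, 0.0, 0.0]))
        with pytest.raises(InsufficientDataError):
            fit_cylinder_axis(_cylinder_cloud(true, 10.0, 5, rng), true)

    def test_collinear_cloud(self):
        axis = Axis3(np.zeros(3), np.array([0.0, 0.0, 1.0]))
        pts = np.outer(np.linspace(0, 1, 20), axis.direction)
        with pytest.raises(InsufficientDataError):
            fit_cylinder_axis(pts, axis)

    def test_equivariance_under_rotation(self, rng):
        """Rotating the cloud rotates the fitted axis identically."""
        true = Axis3(np.array([1.0, 2.0, 3.0]), _unit(np.array([0.8, 0.3, 0.5])))
        pts = _cylinder_cloud(true, 15.0, 150, rng)
        world = Axis3(rng.normal(size=3), _unit(rng.normal(size=3)))
        rot_pts = rotate_about_axis(pts, world, 53.0)
        rot_dir = _unit(rotate_about_axis(true.origin + true.direction, world, 53.0)
                        - rotate_about_axis(true.origin, world, 53.0))
        start = Axis3(rotate_about_axis(true.origin, world, 53.0), rot_dir)
        fit = fit_cylinder_axis(rot_pts, start)
        assert _axis_angle(fit.direction, rot_dir) < 1e-6


def _axis_angle(a, b):
    c = abs(float(np.clip(np.dot(a, b), -1, 1)))
    return float(np.arccos(c))
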