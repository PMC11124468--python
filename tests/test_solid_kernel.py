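"""Solid-kernel contracts: primitives, booleans, smoothing, measurement."""

import math

import numpy as np
import pytest
import trimesh
from hypothesis import given, settings, strategies as st

from pedispine import solid_kernel as sk
from pedispine.fixtures import fixture_profiles


class TestPrimitives:
    def test_unit_cube_volume_and_area(self):
        b = sk.box(1, 1, 1)
        m = sk.measure(b)
        assert m["volume"] == pytest.approx(1.0)
        assert b.mesh.area == pytest.approx(6.0)
        assert m["watertight"] and m["components"] == 1
        assert len(b.faces) == 12

    def test_box_volume_and_validation(self):
        assert sk.box(2, 3, 4).volume == pytest.approx(24.0)
        with pytest.raises(sk.KernelValidationError):
            sk.box(0, 1, 1)

    def test_frustum_box_is_watertight_convex(self):
        f = sk.frustum_box((2, 2), (1, 1), 3)
        # exact frustum volume: h/3 * (A1 + A2 + sqrt(A1*A2))
        assert f.volume == pytest.approx(3 / 3 * (4 + 1 + 2), rel=1e-9)
        assert f.is_watertight
        assert (f.sdf(np.array([[0, 0, 1.5]])) < 0).all()

    def test_revolved_annular_cylinder_matches_closed_form(self):
        prof = np.array([[1, 0], [2, 0], [2, 2], [1, 2]], float)
        s = sk.revolve(prof, 360, segments=512)
        assert s.is_watertight
        assert s.volume == pytest.approx(math.pi * (4 - 1) * 2, rel=2e-3)

    def test_revolved_semicircle_is_a_sphere(self):
        t = np.linspace(-math.pi / 2, math.pi / 2, 97)
        semi = np.column_stack([np.cos(t), np.sin(t)])
        s = sk.revolve(semi, 360, segments=128)
        assert s.is_watertight
        assert s.volume == pytest.approx(4 * math.pi / 3, rel=1e-2)

    def test_partial_sweep_volume_scales_with_angle(self):
        prof = np.array([[1, 0], [2, 0], [2, 2], [1, 2]], float)
        q = sk.revolve(prof, 90, segments=64)
        assert q.is_watertight
        assert q.volume == pytest.approx(math.pi * 3 * 2 / 4, rel=5e-3)

    def test_revolve_rejects_bad_sweep_and_axis_crossing(self):
        prof = np.array([[1, 0], [2, 0], [2, 2], [1, 2]], float)
        with pytest.raises(sk.GeometryError):
            sk.revolve(prof, 0)
        crossing = np.array([[-0.5, 0], [1, 0], [1, 1], [-0.5, 1]], float)
        with pytest.raises(sk.GeometryError):
            sk.revolve(crossing, 360)

    def test_extrusion_volume(self):
        L = np.array([[0, 0], [2, 0], [2, 1], [1, 1], [1, 2], [0, 2]], float)
        p = sk.extrude_polygon(L, 0, 1.5)
        assert p.volume == pytest.approx(4.5)
        assert p.is_watertight


class TestEarclip:
    @given(
        n=st.integers(min_value=3, max_value=24),
        seed=st.integers(min_value=0, max_value=10_000),
    )
    @settings(max_examples=40, deadline=None)
    def test_triangulation_conserves_area_of_star_shaped_polygons(self, n, seed):
        rng = np.random.default_rng(seed)
        ang = np.sort(rng.uniform(0, 2 * math.pi, n))
        if np.min(np.diff(ang, append=ang[0] + 2 * math.pi)) < 1e-3:
            return
        r = rng.uniform(0.5, 2.0, n)
        poly = np.column_stack([r * np.cos(ang), r * np.sin(ang)])
        tris = sk.earclip(poly)
        assert len(tris) == n - 2
        area = sum(
            abs(sk.polygon_area(poly[list(t)])) for t in tris
        )
        assert area == pytest.approx(abs(sk.polygon_area(poly)), rel=1e-9)


class TestBooleans:
    def test_difference_of_nested_cubes(self):
        d = sk.difference(sk.box(1, 1, 1), sk.box(0.5, 0.5, 0.5), pitch=0.02)
        assert d.is_watertight
        assert d.volume == pytest.approx(0.875, rel=0.01)
        assert d.body_count == 2  # outer shell + internal cavity wall

    def test_union_of_disjoint_cubes(self):
        u = sk.union(sk.box(1, 1, 1), sk.box(1, 1, 1, center=(3, 0, 0)), pitch=0.04)
        m = sk.measure(u)
        assert m["components"] == 2
        assert m["volume"] == pytest.approx(2.0, rel=0.015)
        assert m["watertight"]

    def test_union_idempotence(self):
        u = sk.union(sk.box(1, 1, 1), sk.box(1, 1, 1), pitch=0.04)
        assert u.volume == pytest.approx(1.0, rel=0.015)

    def test_union_bounded_by_sum_and_difference_by_minuend(self):
        a = sk.box(2, 1, 1)
        b = sk.box(1, 1, 1, center=(0.75, 0, 0))
        assert sk.union(a, b, pitch=0.04).volume <= a.volume + b.volume + 1e-6
        assert sk.difference(a, b, pitch=0.04).volume <= a.volume + 1e-6

    def test_boolean_volume_conservation(self):
        """difference(a,b) and a-minus-that partition a to within 0.1%."""
        L = np.array([[0, 0], [2, 0], [2, 1], [1, 1], [1, 2], [0, 2]], float)
        a = sk.extrude_polygon(L, 0, 1)
        b = sk.box(1.0, 1.0, 1.0, center=(0.75, 0.75, 0.5))
        d1 = sk.difference(a, b, pitch=0.02)
        d2 = sk.difference(a, d1, pitch=0.02)
        assert abs(d1.volume + d2.volume - a.volume) / a.volume < 1e-3

    def test_boolean_rejects_solids_without_field(self):
        rounded = sk.fillet_edges(sk.box(1, 1, 1), 0.1)
        rounded.sdf = None  # a mesh-only solid cannot enter implicit CSG
        with pytest.raises(sk.GeometryError):
            sk.union(rounded, sk.box(1, 1, 1))


class TestFillet:
    def test_rounded_cube_contract(self):
        f = sk.fillet_edges(sk.box(1, 1, 1), 0.1)
        assert f.is_watertight
        # exact rounded-cube volume at r=0.1 is 0.9756; smoothing must stay
        # in the contractual band below the sharp cube
        assert 0.85 < f.volume < 1.0
        before = np.degrees(sk.box(1, 1, 1).mesh.face_adjacency_angles.max())
        after = np.degrees(f.mesh.face_adjacency_angles.max())
        assert after < before

    def test_repeat_fillet_nearly_idempotent(self):
        f1 = sk.fillet_edges(sk.box(1, 1, 1), 0.1)
        f2 = sk.fillet_edges(f1, 0.1)
        assert abs(f2.volume - f1.volume) / f1.volume < 0.01

    def test_invalid_radii(self):
        with pytest.raises(sk.KernelValidationError):
            sk.fillet_edges(sk.box(1, 1, 1), 0.0)
        with pytest.raises(sk.GeometryError):
            sk.fillet_edges(sk.box(1, 1, 1), 0.6)


class TestMeasurementAndDistance:
    def test_icosphere_volume_within_half_percent(self):
        s = sk.sphere(1.0, subdivisions=4)
        assert s.volume == pytest.approx(4 * math.pi / 3, rel=5e-3)

    def test_min_distance_examples(self):
        a, b = sk.sphere(1.0, (0, 0, 0)), sk.sphere(1.0, (3, 0, 0))
        assert sk.min_distance(a, b).distance == pytest.approx(1.0, abs=5e-3)
        touching = sk.min_distance(sk.box(1, 1, 1), sk.box(1, 1, 1, center=(1, 0, 0)))
        assert touching.distance == pytest.approx(0.0, abs=1e-9)
        offset = sk.min_distance(sk.box(1, 1, 1), sk.box(1, 1, 1, center=(1.5, 0, 0)))
        assert offset.distance == pytest.approx(0.5, abs=1e-9)
        overlap = sk.min_distance(sk.box(1, 1, 1), sk.box(1, 1, 1, center=(0.5, 0, 0)))
        assert overlap.distance == 0.0 and overlap.overlapping

    def test_min_distance_against_sampled_brute_force(self):
        a = sk.cylinder(1.0, 2.0, center=(0, 0, 0), sections=96)
        b = sk.box(1, 1, 1, center=(2.2, 0.4, 0.3))
        fast = sk.min_distance(a, b).distance
        rng = np.random.default_rng(7)
        pa, _ = trimesh.sample.sample_surface(a.mesh, 100_000, seed=1)
        pb, _ = trimesh.sample.sample_surface(b.mesh, 100_000, seed=2)
        from scipy.spatial import cKDTree

        brute = cKDTree(pa).query(pb)[0].min()
        assert abs(fast - brute) < 0.02
        assert fast <= brute + 1e-9

    def test_monte_carlo_volume_oracle(self):
        """Divergence-theorem volume vs inside-test Monte Carlo, 3-sigma."""
        for solid in (
            sk.box(1.2, 0.7, 2.0),
            sk.extrude_polygon(
                np.array([[0, 0], [2, 0], [2, 1], [1, 1], [1, 2], [0, 2]], float), 0, 1
            ),
            sk.difference(sk.box(1, 1, 1), sk.box(0.5, 0.5, 0.5), pitch=0.015),
        ):
            est, sigma = sk.monte_carlo_volume(solid, n=1_000_000, seed=11)
            assert abs(solid.volume - est) <= 3 * sigma + 1e-9

    def test_rigid_motion_invariance(self):
        s = sk.extrude_polygon(
            np.array([[0, 0], [2, 0], [2, 1], [1, 1], [1, 2], [0, 2]], float), 0, 1
        )
        m = trimesh.transformations.rotation_matrix(0.7, (1, 2, 3), point=(0.3, -1, 2))
        moved = s.transformed(m)
        assert moved.volume == pytest.approx(s.volume, rel=1e-9)
        probe = np.array([[0.5, 0.5, 0.5]])
        world = probe @ m[:3, :3].T + m[:3, 3]
        assert moved.sdf(world) == pytest.approx(s.sdf(probe), abs=1e-9)


class TestFixtures:
    def test_fixture_measures(self):
        fx = fixture_profiles()
        assert fx["unit_square"][0].area == pytest.approx(1.0)
        # inscribed 64-gon of the r=2 circle: within 0.5% of 4*pi
        assert fx["circle_r2"][0].area == pytest.approx(4 * math.pi, rel=5e-3)
        assert fx["l_profile"][0].area == pytest.approx(3.0)
        assert fx["l_prism"][0].volume == pytest.approx(3.0)
        outer, inner = fx["nested_boxes"][0]
        d = sk.difference(outer, inner, pitch=0.02)
        assert d.volume == pytest.approx(fx["nested_boxes"][1], rel=0.01)
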