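"""Projection and spherical-triangulation geometry."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fundusphere.geometry import (
    EyeModel,
    FundusFrame,
    GeometryError,
    OutOfFieldError,
    SingularityError,
    DegenerateConfigurationError,
    forward_project,
    geodesic_distance,
    reverse_project,
    spherical_angle,
    spherical_area,
)

from conftest import random_infield_pixels, random_sphere_points


class TestEyeModel:
    def test_radius_is_half_axial_length(self):
        assert EyeModel(24.0).radius_mm == 12.0
        assert EyeModel(22.0).radius_mm == 11.0

    @pytest.mark.parametrize("al", [19.0, 27.5, -1.0, 0.0])
    def test_out_of_range_axial_lengths_rejected(self, al):
        with pytest.raises(GeometryError):
            EyeModel(al)

    def test_range_enforcement_is_configurable(self):
        assert EyeModel(28.5, check_range=False).radius_mm == 14.25


class TestProjection:
    def test_image_center_maps_to_posterior_pole(self, eye24, frame1000):
        p = reverse_project(frame1000.center_px, frame1000, eye24)
        assert np.allclose(p, [0.0, 0.0, -1.0], atol=1e-12)

    def test_circle_edge_maps_to_half_fov_polar_angle(self, eye24, frame1000):
        # forward formula rho = 2 R tan(theta/2) at theta = 100 deg calibrates the rim
        cx, cy = frame1000.center_px
        p = reverse_project((cx + frame1000.radius_px, cy), frame1000, eye24)
        polar = np.degrees(np.arccos(-p[2]))
        assert polar == pytest.approx(100.0, abs=1e-9)

    def test_plane_offset_closed_form(self, eye24, frame1000):
        # point at polar 100 deg, azimuth 0, R = 12 mm -> plane X = 2*12*tan(50 deg)
        th = np.radians(100.0)
        point = np.array([np.sin(th), 0.0, -np.cos(th)])
        px = forward_project(point, frame1000, eye24)
        scale = frame1000.plane_scale_px_per_mm(eye24)
        plane_x = (px[0] - frame1000.center_px[0]) / scale
        assert plane_x == pytest.approx(2 * 12 * np.tan(np.radians(50.0)), abs=1e-9)
        assert plane_x == pytest.approx(28.60, abs=5e-3)

    def test_round_trip_identity_on_pixels(self, eye24, frame1000, rng):
        px = random_infield_pixels(rng, frame1000, 1000)
        back = forward_project(reverse_project(px, frame1000, eye24), frame1000, eye24)
        assert np.abs(back - px).max() < 1e-9

    def test_round_trip_identity_on_sphere(self, eye24, frame1000, rng):
        pts = random_sphere_points(rng, 1000, max_colat_deg=99.9)
        again = reverse_project(forward_project(pts, frame1000, eye24), frame1000, eye24)
        assert np.abs(again - pts).max() < 1e-12

    def test_out_of_field_pixel_rejected(self, eye24, frame1000):
        with pytest.raises(OutOfFieldError):
            reverse_project((2.0, 2.0), frame1000, eye24)  # corner, outside circle

    def test_anterior_pole_has_no_image(self, eye24, frame1000):
        with pytest.raises(SingularityError):
            forward_project((0.0, 0.0, 1.0), frame1000, eye24)

    def test_os_mirror_flips_horizontal_axis(self):
        frame = FundusFrame(1000, 1000, mirror_os=True)
        od = EyeModel(24.0, "OD")
        os_ = EyeModel(24.0, "OS")
        p_od = reverse_project((700.0, 499.5), frame, od)
        p_os = reverse_project((700.0, 499.5), frame, os_)
        assert np.allclose(p_os, p_od * [-1.0, 1.0, 1.0])

    @given(st.floats(22.0, 26.97), st.floats(22.0, 26.97))
    def test_distance_scales_linearly_with_axial_length(self, al_a, al_b):
        """The core correction: same pixels, distance ratio = axial-length ratio."""
        frame = FundusFrame(1000, 1000)
        pix = np.array([[300.0, 400.0], [650.0, 580.0]])
        def dist(al):
            eye = EyeModel(al)
            p = reverse_project(pix, frame, eye)
            return geodesic_distance(p[0], p[1], eye).distance_mm
        assert dist(al_a) * al_b == pytest.approx(dist(al_b) * al_a, rel=1e-12)

    def test_angles_are_axial_length_invariant(self, frame1000, rng):
        pix = random_infield_pixels(rng, frame1000, 9).reshape(3, 3, 2)
        for tri in pix:
            angles = []
            for al in (22.0, 24.0):
                p = reverse_project(tri, frame1000, EyeModel(al))
                angles.append(spherical_angle(p[0], p[1], p[2]))
            assert abs(angles[0] - angles[1]) < 1e-9


class TestGeodesic:
    def test_coincident_points_zero_distance(self, eye24):
        p = np.array([0.0, 0.0, -1.0])
        assert geodesic_distance(p, p, eye24).distance_mm == 0.0

    def test_antipodal_distance_is_pi_r(self, eye24):
        g = geodesic_distance([0, 0, -1.0], [0, 0, 1.0], eye24)
        assert g.distance_mm == pytest.approx(np.pi * 12.0, abs=1e-12)
        assert g.distance_mm == pytest.approx(37.699, abs=1e-3)

    def test_axial_length_worked_example(self):
        """A separation reading 14 mm on the fixed 24-mm eye reads 12.833 mm at AL 22."""
        theta = 14.0 / 12.0  # rad, fixed pixel geometry
        p = np.array([np.sin(theta), 0.0, -np.cos(theta)])
        pole = np.array([0.0, 0.0, -1.0])
        d22 = geodesic_distance(pole, p, EyeModel(22.0)).distance_mm
        assert d22 == pytest.approx(12.833, abs=1e-3)
        assert 14.0 - d22 == pytest.approx(1.167, abs=1e-3)  # ~1 mm to the nearest mm

    def test_symmetry_and_triangle_inequality(self, rng, eye24):
        pts = random_sphere_points(rng, 30)
        for a, b, c in pts.reshape(10, 3, 3):
            dab = geodesic_distance(a, b, eye24).distance_mm
            dba = geodesic_distance(b, a, eye24).distance_mm
            assert dab == pytest.approx(dba, abs=1e-12)
            dac = geodesic_distance(a, c, eye24).distance_mm
            dcb = geodesic_distance(c, b, eye24).distance_mm
            assert dab <= dac + dcb + 1e-12

    def test_non_unit_input_rejected(self, eye24):
        with pytest.raises(GeometryError):
            geodesic_distance([0, 0, -2.0], [0, 0, 1.0], eye24)


class TestSphericalAngle:
    def test_collinear_gives_zero(self):
        v = np.array([0.0, 0.0, -1.0])
        th1, th2 = np.radians(30.0), np.radians(60.0)
        a = np.array([np.sin(th1), 0, -np.cos(th1)])
        c = np.array([np.sin(th2), 0, -np.cos(th2)])
        assert spherical_angle(v, c, a) == pytest.approx(0.0, abs=1e-9)

    def test_orthogonal_meridians_give_90(self):
        vertex = np.array([1.0, 0.0, 0.0])  # on equator
        along_equator = np.array([0.0, 1.0, 0.0])
        north = np.array([0.0, 0.0, 1.0])
        assert spherical_angle(vertex, along_equator, north) == pytest.approx(90.0, abs=1e-12)

    def test_degenerate_vertex_rejected(self):
        v = np.array([0.0, 0.0, -1.0])
        with pytest.raises(DegenerateConfigurationError):
            spherical_angle(v, v, np.array([1.0, 0.0, 0.0]))

    def test_signed_angle_positive_toward_superior(self):
        vertex = np.array([0.0, 0.0, -1.0])
        ref = np.array([np.sin(0.5), 0.0, -np.cos(0.5)])  # temporal
        up = np.array([0.0, np.sin(0.5), -np.cos(0.5)])  # superior
        assert spherical_angle(vertex, ref, up, signed=True) == pytest.approx(90.0)
        assert spherical_angle(vertex, up, ref, signed=True) == pytest.approx(-90.0)

    def test_girard_consistency_with_area(self, rng, eye24):
        """Angle sum - 180 deg equals area / R^2 (spherical excess)."""
        for tri in random_sphere_points(rng, 30).reshape(10, 3, 3):
            a, b, c = tri
            angles = (
                spherical_angle(a, b, c)
                + spherical_angle(b, c, a)
                + spherical_angle(c, a, b)
            )
            excess = np.radians(angles - 180.0)
            area = spherical_area(tri, eye24)
            assert area == pytest.approx(excess * eye24.radius_mm**2, rel=1e-8)


class TestSphericalArea:
    def test_octant_is_eighth_of_sphere(self, eye24):
        tri = np.eye(3)
        assert spherical_area(tri, eye24) == pytest.approx((np.pi / 2) * 144.0, rel=1e-12)
        assert spherical_area(tri, eye24) == pytest.approx(226.19, abs=5e-3)

    def test_small_triangle_approaches_planar_area(self, rng, eye24):
        # arcs < 2 degrees: spherical and planar areas agree within 1 %
        base = np.array([0.0, 0.0, -1.0])
        for _ in range(10):
            d = rng.uniform(-0.015, 0.015, (3, 2))  # < ~1 deg offsets
            tri = np.stack(
                [np.array([dx, dy, -np.sqrt(1 - dx**2 - dy**2)]) for dx, dy in d]
            )
            e1, e2 = tri[1, :2] - tri[0, :2], tri[2, :2] - tri[0, :2]
            planar = 0.5 * abs(e1[0] * e2[1] - e1[1] * e2[0]) * eye24.radius_mm**2
            if planar < 1e-6:
                continue
            assert spherical_area(tri, eye24) == pytest.approx(planar, rel=0.01)

    def test_degenerate_polygons_rejected(self, eye24):
        p = np.array([0.0, 0.0, -1.0])
        q = np.array([1.0, 0.0, 0.0])
        with pytest.raises(GeometryError):
            spherical_area([p, q], eye24)
        with pytest.raises(GeometryError):
            spherical_area([p, p, q], eye24)
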