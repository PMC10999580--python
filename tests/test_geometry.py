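import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from brachytrack.errors import ConfigurationError, GeometryError
from brachytrack.geometry import (
    CollimatorSpec,
    DetectorSpec,
    PanelPose,
    build_layout,
    default_layout,
    focal_length,
    hole_axis,
    pixel_footprint,
)


class TestSpecs:
    def test_pitch_is_hole_plus_septum(self):
        assert CollimatorSpec().pitch == pytest.approx(0.6)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"hole_size_d": 0.0},
            {"septal_thickness_t": -0.1},
            {"height_h": 0.0},
            {"acceptance_angle": 0.0},
            {"acceptance_angle": 180.0},
        ],
    )
    def test_invalid_collimator_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            CollimatorSpec(**kwargs)

    def test_active_pixel_cannot_exceed_pitch(self):
        with pytest.raises(ConfigurationError):
            DetectorSpec(active_pixel_size=0.7, pixel_pitch=0.6)


class TestBuildLayout:
    def test_default_ring_panel_centers(self):
        layout = default_layout(z_offsets=[0.0] * 6)
        c270 = layout[0].entrance_center
        c90 = layout[5].entrance_center
        np.testing.assert_allclose(c270, [0.0, -500.0, 0.0], atol=1e-9)
        np.testing.assert_allclose(c90, [0.0, 500.0, 0.0], atol=1e-9)

    def test_single_panel_center_and_normal(self):
        layout = build_layout(1.0, [0.0], [0.0])
        np.testing.assert_allclose(layout[0].entrance_center, [1.0, 0.0, 0.0], atol=1e-12)
        np.testing.assert_allclose(layout[0].pose.orientation, [-1.0, 0.0, 0.0], atol=1e-12)

    def test_opposed_panels_with_z_offsets(self):
        layout = build_layout(100.0, [0.0, 180.0], [10.0, -10.0])
        np.testing.assert_allclose(layout[0].entrance_center, [100.0, 0.0, 10.0], atol=1e-9)
        np.testing.assert_allclose(layout[1].entrance_center, [-100.0, 0.0, -10.0], atol=1e-9)
        np.testing.assert_allclose(layout[0].pose.orientation, [-1, 0, 0], atol=1e-12)
        np.testing.assert_allclose(layout[1].pose.orientation, [1, 0, 0], atol=1e-12)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ConfigurationError):
            build_layout(500.0, [0.0, 90.0], [0.0])

    def test_non_increasing_ring_angles_rejected(self):
        with pytest.raises(ConfigurationError):
            build_layout(500.0, [0.0, 240.0, 120.0], [0.0, 0.0, 0.0])

    def test_panel_normals_hit_the_ring_axis(self):
        """Each panel faces the z-shifted point (0, 0, z_k) on the axis."""
        for panel in default_layout():
            c = panel.entrance_center
            n = panel.pose.orientation
            t = -(c[0] * n[0] + c[1] * n[1]) / (n[0] ** 2 + n[1] ** 2)
            hit = c + t * n
            np.testing.assert_allclose(hit, [0.0, 0.0, panel.pose.z_offset], atol=1e-9)


class TestFocalLength:
    def test_closed_form_at_45_degrees(self, detector, collimator):
        # hand calculation: 12.9 / tan(22.5 deg) = 31.1434 mm
        assert focal_length(collimator, detector) == pytest.approx(31.1434, abs=1e-3)

    def test_right_angle_gives_half_face(self, detector):
        col = CollimatorSpec(acceptance_angle=90.0)
        assert focal_length(col, detector) == pytest.approx(detector.face_size / 2)

    def test_parallel_hole_limit(self, detector):
        assert focal_length(CollimatorSpec(acceptance_angle=0.01), detector) > 1e5

    def test_strictly_decreasing_in_acceptance_angle(self, detector):
        angles = np.linspace(5.0, 175.0, 35)
        f = [focal_length(CollimatorSpec(acceptance_angle=a), detector) for a in angles]
        assert np.all(np.diff(f) < 0)

    def test_override_bypasses_angle(self, detector):
        col = CollimatorSpec(focal_length_override=58.9)
        assert focal_length(col, detector) == 58.9


class TestHoleAxis:
    def test_central_hole_of_odd_array_along_normal(self):
        col = CollimatorSpec(holes_per_side=39)
        layout = build_layout(500.0, [0.0], [0.0], None, col)
        ray = hole_axis(layout[0], 19, 19)
        np.testing.assert_allclose(ray.direction, [-1.0, 0.0, 0.0], atol=1e-12)

    def test_two_point_construction_oracle(self, single_panel_layout):
        """Direction equals the independent focal-point-to-hole-center chord."""
        panel = single_panel_layout[0]
        ray = hole_axis(panel, 0, 37)
        chord = ray.point - panel.focal_point
        np.testing.assert_allclose(
            ray.direction, chord / np.linalg.norm(chord), atol=1e-12
        )
        # corner hole must diverge from the panel normal by atan(r_corner / F)
        off = panel.hole_offsets()
        r_corner = math.hypot(off[37], off[0])
        expected = math.atan2(r_corner, panel.focal_len)
        got = math.acos(np.dot(ray.direction, panel.pose.orientation))
        assert got == pytest.approx(expected, abs=1e-12)

    def test_mirror_holes_reflect_through_axis(self, single_panel_layout):
        panel = single_panel_layout[0]
        a = hole_axis(panel, 3, 5).direction
        b = hole_axis(panel, 34, 32).direction
        # reflection through the panel axis flips both transverse components
        axes = panel.axes
        ta = axes.T @ a
        tb = axes.T @ b
        np.testing.assert_allclose(ta[:2], -tb[:2], atol=1e-12)
        assert ta[2] == pytest.approx(tb[2])

    def test_index_out_of_range(self, single_panel_layout):
        with pytest.raises(IndexError):
            hole_axis(single_panel_layout[0], 38, 0)

    @pytest.mark.parametrize("distance", [0.0, 100.0, 500.0])
    def test_hole_axes_tile_by_similar_triangles(self, single_panel_layout, distance):
        """Traced to a plane D mm past the entrance face, the hole-axis grid
        spans the detector-face grid scaled by (F + h + D) / F."""
        panel = single_panel_layout[0]
        F, h = panel.focal_len, panel.collimator.height_h
        plane = F + h + distance
        pts = []
        for ij in [(0, 0), (0, 37), (37, 0), (37, 37)]:
            ray = hole_axis(panel, *ij)
            local_p = panel.to_panel(ray.point)
            local_d = panel.axes.T @ ray.direction
            t = (plane - local_p[2]) / local_d[2]
            pts.append((local_p + t * local_d)[:2])
        pts = np.array(pts)
        span = pts.max(axis=0) - pts.min(axis=0)
        expected = 37 * panel.collimator.pitch * plane / F
        np.testing.assert_allclose(span, expected, rtol=1e-12)


class TestPixelFootprint:
    def test_zero_distance_is_active_area(self, single_panel_layout):
        panel = single_panel_layout[0]
        quad = pixel_footprint(panel, 10, 20, 0.0)
        side = np.linalg.norm(quad[1] - quad[0])
        assert side == pytest.approx(panel.detector.active_pixel_size, abs=1e-12)

    def test_footprint_grows_monotonically(self, single_panel_layout):
        panel = single_panel_layout[0]
        sides = []
        for dist in (0.0, 50.0, 200.0, 530.0):
            quad = pixel_footprint(panel, 19, 19, dist)
            sides.append(np.linalg.norm(quad[1] - quad[0]))
        assert np.all(np.diff(sides) > 0)

    def test_similar_triangles_oracle_at_isocenter(self, single_panel_layout):
        """Footprint side at distance D equals active_size * (F + D) / F."""
        panel = single_panel_layout[0]
        F = panel.focal_len
        D = panel.collimator.height_h + 500.0  # the isocenter plane
        quad = pixel_footprint(panel, 19, 19, D)
        side = np.linalg.norm(quad[1] - quad[0])
        assert side == pytest.approx(0.5 * (F + D) / F, rel=1e-12)

    def test_plane_behind_detector_rejected(self, single_panel_layout):
        with pytest.raises(GeometryError):
            pixel_footprint(single_panel_layout[0], 0, 0, -1.0)


class TestTransforms:
    @given(
        st.floats(-200, 200),
        st.floats(-200, 200),
        st.floats(-200, 200),
        st.sampled_from([0, 1, 2, 3, 4, 5]),
    )
    def test_world_panel_roundtrip(self, x, y, z, k):
        panel = default_layout()[k]
        p = np.array([x, y, z])
        np.testing.assert_allclose(panel.to_world(panel.to_panel(p)), p, atol=1e-9)

    def test_frame_is_right_handed_orthonormal(self, ring_layout):
        for panel in ring_layout:
            R = panel.axes
            np.testing.assert_allclose(R.T @ R, np.eye(3), atol=1e-12)
            assert np.linalg.det(R) == pytest.approx(1.0)

    def test_isocenter_maps_to_panel_axis(self, ring_layout):
        for panel in ring_layout:
            local = panel.to_panel(np.array([0.0, 0.0, panel.pose.z_offset]))
            assert abs(local[0]) < 1e-9 and abs(local[1]) < 1e-9
            expected = panel.pose.radius + panel.collimator.height_h + panel.focal_len
            assert local[2] == pytest.approx(expected)


def test_source_state_validation():
    from brachytrack.geometry import SourceState

    with pytest.raises(ConfigurationError):
        SourceState(diameter=0.0)
    with pytest.raises(ConfigurationError):
        SourceState(axis=[0, 0, 0])
    s = SourceState(axis=[0, 0, 2.0])
    np.testing.assert_allclose(s.axis, [0, 0, 1.0])
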