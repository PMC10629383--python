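import math

import numpy as np
import pytest
from shapely.affinity import rotate, translate
from shapely.geometry import Polygon, box

from skystrip.geometry import (
    CameraModel,
    HorizonError,
    Pose,
    cut_by_segments,
    dissolve_coverage,
    forward_overlap,
    image_footprint,
    map_observer_sighting,
    min_bounding_width,
    nadir_footprint_area,
    observer_effective_area,
    project_pixel_to_ground,
    schedule_capture_interval,
    side_overlap,
)


class TestProjectPixel:
    def test_nadir_centre_identity(self, nadir_pose, camera):
        e, n = project_pixel_to_ground(nadir_pose, camera, camera.centre_pixel)
        assert e == pytest.approx(0.0, abs=1e-9)
        assert n == pytest.approx(0.0, abs=1e-9)

    def test_mount_tilt_across_track_offset(self, nadir_pose, tilted_camera):
        e, n = project_pixel_to_ground(nadir_pose, tilted_camera, tilted_camera.centre_pixel)
        assert e == pytest.approx(396.0 * math.tan(math.radians(11.5)), rel=1e-9)
        assert n == pytest.approx(0.0, abs=1e-6)

    def test_tilted_across_track_span(self, tilted_camera):
        # half-FOV across-track = atan(0.0116 / 0.050) = 13.06 deg
        pose = Pose(0.0, 0.0, 427.0)
        half_fov = math.degrees(math.atan(0.0116 / 0.050))
        cx, cy = tilted_camera.centre_pixel
        near, _ = project_pixel_to_ground(pose, tilted_camera, (0, cy))
        far, _ = project_pixel_to_ground(pose, tilted_camera, (6016, cy))
        assert near == pytest.approx(427 * math.tan(math.radians(11.5 - half_fov)), rel=1e-6)
        assert far == pytest.approx(427 * math.tan(math.radians(11.5 + half_fov)), rel=1e-6)
        assert near == pytest.approx(-11.64, abs=0.05)
        assert far == pytest.approx(195.1, abs=0.1)

    def test_horizon_error(self, camera):
        pose = Pose(0, 0, 396, pitch=95.0)
        with pytest.raises(HorizonError):
            project_pixel_to_ground(pose, camera, camera.centre_pixel)

    def test_azimuth_rotates_ground_point(self, camera):
        pose0 = Pose(0, 0, 396, azimuth=0.0)
        pose90 = Pose(0, 0, 396, azimuth=90.0)
        p0 = project_pixel_to_ground(pose0, camera, (0, 0))
        p90 = project_pixel_to_ground(pose90, camera, (0, 0))
        # clockwise rotation by 90 deg maps (e, n) -> (n, -e)
        assert p90[0] == pytest.approx(p0[1], abs=1e-9)
        assert p90[1] == pytest.approx(-p0[0], abs=1e-9)


class TestFootprint:
    def test_nadir_rectangle_dimensions(self, nadir_pose, camera):
        fp = image_footprint(nadir_pose, camera)
        xs = [c[0] for c in fp.corners]
        ys = [c[1] for c in fp.corners]
        assert max(xs) - min(xs) == pytest.approx(396 * 0.0232 / 0.050, rel=1e-9)
        assert max(ys) - min(ys) == pytest.approx(396 * 0.0154 / 0.050, rel=1e-9)

    def test_nadir_area_closed_form(self, nadir_pose, camera):
        fp = image_footprint(nadir_pose, camera)
        expect = nadir_footprint_area(396, 0.0232, 0.0154, 0.050)
        assert fp.polygon.area == pytest.approx(expect, rel=1e-9)

    def test_scale_equivariance_with_altitude(self, camera):
        fp1 = image_footprint(Pose(0, 0, 200), camera)
        fp2 = image_footprint(Pose(0, 0, 400), camera)
        for c1, c2 in zip(fp1.corners, fp2.corners):
            assert c2[0] == pytest.approx(2 * c1[0], rel=1e-9)
            assert c2[1] == pytest.approx(2 * c1[1], rel=1e-9)

    def test_corners_counter_clockwise(self, nadir_pose, camera):
        fp = image_footprint(nadir_pose, camera)
        assert Polygon(fp.corners).exterior.is_ccw

    def test_gsd_nadir(self, nadir_pose, camera):
        fp = image_footprint(nadir_pose, camera)
        assert fp.gsd_centre == pytest.approx(396 * (0.0232 / 6016) / 0.050, rel=1e-6)

    def test_gsd_tilted(self, nadir_pose, tilted_camera):
        fp = image_footprint(nadir_pose, tilted_camera)
        nadir_gsd = 396 * (0.0232 / 6016) / 0.050
        assert fp.gsd_centre == pytest.approx(
            nadir_gsd / math.cos(math.radians(11.5)) ** 2, rel=1e-3
        )

    @pytest.mark.parametrize("theta", [17.0, 123.4, 250.0])
    def test_azimuth_equivariance(self, camera, theta):
        fp0 = image_footprint(Pose(0, 0, 396), camera)
        fpr = image_footprint(Pose(0, 0, 396, azimuth=theta), camera)
        rotated = rotate(fp0.polygon, -theta, origin=(0, 0))  # clockwise
        assert rotated.symmetric_difference(fpr.polygon).area < 1e-6


class TestOverlaps:
    def test_identical_footprints(self, nadir_pose, camera):
        fp = image_footprint(nadir_pose, camera)
        assert forward_overlap(fp, fp) == pytest.approx(1.0)

    def test_forty_percent_shift(self):
        a = box(0, 0, 183.7, 121.97)
        b = translate(a, yoff=121.97 * 0.6)
        assert forward_overlap(a, b) == pytest.approx(0.40, rel=1e-9)

    def test_disjoint_zero(self):
        a = box(0, 0, 183.7, 121.97)
        b = translate(a, yoff=200.0)
        assert forward_overlap(a, b) == 0.0

    def test_scheduled_interval_hits_target_lap(self, camera, config):
        interval = schedule_capture_interval(396, 0.050, 0.0154, 0.40, 30.87)
        fp1 = image_footprint(Pose(0, 0, 396), camera)
        fp2 = image_footprint(Pose(0, 30.87 * interval, 396), camera)
        assert forward_overlap(fp1, fp2) == pytest.approx(0.40, abs=1e-3)

    def test_side_overlap_strips(self):
        a = box(0, 0, 200, 1000)
        b = box(176, 0, 376, 1000)
        assert side_overlap(a, b) == pytest.approx(0.12, rel=1e-9)

    def test_side_overlap_disjoint_and_identical(self):
        a = box(0, 0, 200, 1000)
        assert side_overlap(a, translate(a, xoff=300)) == 0.0
        assert side_overlap(a, a) == pytest.approx(1.0)

    def test_side_overlap_empty_errors(self):
        with pytest.raises(ValueError):
            side_overlap(Polygon(), box(0, 0, 1, 1))


class TestMinBoundingWidth:
    def test_axis_aligned_rectangle(self):
        assert min_bounding_width(box(0, 0, 200, 150)) == pytest.approx(200.0)

    def test_rotated_rectangle(self):
        r = rotate(box(0, 0, 200, 150), 37.0, origin="centroid")
        assert min_bounding_width(r) == pytest.approx(200.0, rel=1e-6)

    def test_square(self):
        assert min_bounding_width(box(0, 0, 100, 100)) == pytest.approx(100.0)

    def test_rigid_motion_invariance(self, rng):
        pts = rng.uniform(0, 100, (8, 2))
        poly = Polygon(pts).convex_hull
        w0 = min_bounding_width(poly)
        moved = translate(rotate(poly, 63.0, origin="centroid"), xoff=512, yoff=-77)
        assert min_bounding_width(moved) == pytest.approx(w0, rel=1e-9)

    def test_degenerate_errors(self):
        with pytest.raises(ValueError):
            min_bounding_width(Polygon())


class TestDissolve:
    def test_disjoint_sum(self):
        a, b = box(0, 0, 1000, 1000), box(2000, 0, 3000, 1000)
        _, area = dissolve_coverage([a, b])
        assert area == pytest.approx(2e6)

    def test_forty_percent_overlap(self):
        a = box(0, 0, 1000, 1000)
        b = translate(a, xoff=600)
        _, area = dissolve_coverage([a, b])
        assert area == pytest.approx(1.6e6, rel=1e-12)

    def test_idempotent(self):
        a = box(0, 0, 1000, 1000)
        _, area = dissolve_coverage([a] * 7)
        assert area == pytest.approx(1e6)

    def test_union_at_most_sum(self, rng):
        polys = [
            box(x, y, x + 300, y + 300)
            for x, y in rng.uniform(0, 1000, (10, 2))
        ]
        _, area = dissolve_coverage(polys)
        assert area <= sum(p.area for p in polys) + 1e-9

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            dissolve_coverage([])


class TestCutBySegments:
    def test_single_segment_total(self):
        cov = box(-200, 0, 200, 4000)
        areas = cut_by_segments(cov, (0, 0), 0.0, [0, 4000])
        assert areas[0] == pytest.approx(cov.area, rel=1e-9)

    def test_midpoint_halves(self):
        cov = box(-200, 0, 200, 4000)
        areas = cut_by_segments(cov, (0, 0), 0.0, [0, 2000, 4000])
        assert areas[0] == pytest.approx(areas[1], rel=1e-9)

    def test_three_cuts(self):
        cov = box(-200, 0, 200, 4000)
        areas = cut_by_segments(cov, (0, 0), 0.0, [0, 1000, 2500, 4000])
        assert areas == pytest.approx([0.4e6, 0.6e6, 0.6e6], rel=1e-9)

    def test_sum_matches_total(self, rng):
        cov = box(-180, 0, 220, 5000)
        bounds = [0] + sorted(rng.uniform(1, 4999, 5).tolist()) + [5000]
        areas = cut_by_segments(cov, (0, 0), 0.0, bounds)
        assert sum(areas) == pytest.approx(cov.area, rel=1e-6)

    def test_unordered_boundaries_error(self):
        with pytest.raises(ValueError):
            cut_by_segments(box(0, 0, 1, 1), (0, 0), 0.0, [10, 5])


class TestScheduling:
    def test_reference_interval(self):
        # 427 m, 50 mm, 15.4 mm sensor, 40% lap, 60 kn -> 131.5 * 0.6 / 30.87
        assert schedule_capture_interval(427, 0.050, 0.0154, 0.40, 30.87) == pytest.approx(
            2.556, abs=0.001
        )

    def test_zero_lap_full_frame(self):
        iv = schedule_capture_interval(427, 0.050, 0.0154, 0.0, 30.87)
        assert iv == pytest.approx(427 * 0.0154 / 0.050 / 30.87, rel=1e-12)

    def test_speed_proportionality(self):
        a = schedule_capture_interval(427, 0.050, 0.0154, 0.40, 30.87)
        b = schedule_capture_interval(427, 0.050, 0.0154, 0.40, 61.74)
        assert a == pytest.approx(2 * b, rel=1e-12)

    def test_lap_one_errors(self):
        with pytest.raises(ValueError):
            schedule_capture_interval(427, 0.050, 0.0154, 1.0, 30.87)


class TestObserverArea:
    def test_nominal(self):
        assert observer_effective_area(1000, 152) == pytest.approx(409_000.0)

    def test_altitude_fraction(self):
        assert observer_effective_area(2000, 160) == pytest.approx(
            (160 / 152) * 2000 * 409, rel=1e-12
        )

    def test_zero_length_errors(self):
        with pytest.raises(ValueError):
            observer_effective_area(0, 152)


class TestMapObserverSighting:
    def setup_method(self):
        self.t = np.array([0.0, 100.0])
        self.e = np.array([0.0, 0.0])
        self.n = np.array([0.0, 3000.0])

    def test_port_zone_zero(self):
        pt = map_observer_sighting(0.0, "port", 0, self.t, self.e, self.n)
        assert pt == pytest.approx((-173.0, 0.0))

    def test_starboard_mirror(self):
        p = map_observer_sighting(50.0, "port", 2, self.t, self.e, self.n)
        s = map_observer_sighting(50.0, "starboard", 2, self.t, self.e, self.n)
        assert s[0] == pytest.approx(-p[0])
        assert s[1] == pytest.approx(p[1])

    def test_interpolated_position(self):
        pt = map_observer_sighting(50.0, "port", 0, self.t, self.e, self.n)
        assert pt[1] == pytest.approx(1500.0)

    def test_altitude_scaling(self):
        pt = map_observer_sighting(
            0.0, "port", 0, self.t, self.e, self.n, altitude_fraction=160 / 152
        )
        assert pt[0] == pytest.approx(-173.0 * 160 / 152)

    def test_time_outside_track_errors(self):
        with pytest.raises(ValueError):
            map_observer_sighting(500.0, "port", 0, self.t, self.e, self.n)
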