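"""Landmark location, distance measurement and feature computation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctvshift import (Contour, GeometryError, Point2D, compute_features,
                      locate_feature_points, measure_distances, prostate_center)
from ctvshift.features import DistanceSet, FeatureNotMeasurable

from conftest import rectangle


class TestFeaturePoints:
    def test_stated_criterion_on_four_vertices(self):
        bone = Contour([(0, 0), (10, 5), (15, -35), (2, -40)])
        pts = locate_feature_points(bone)
        assert pts.S.as_tuple() == (0, 0)
        assert pts.I.as_tuple() == (2, -40)

    def test_square_corners(self):
        bone = rectangle(10, 20, -30, 0)
        pts = locate_feature_points(bone)
        assert pts.S.as_tuple() == (10, 0)      # posterior-superior corner
        assert pts.I.as_tuple() == (10, -30)    # posterior-inferior corner

    @given(da=st.floats(-50, 50), ds=st.floats(-50, 50))
    @settings(max_examples=25, deadline=None)
    def test_translation_equivariance(self, da, ds):
        bone = Contour([(0, 0), (10, 5), (15, -35), (2, -40)])
        pts = locate_feature_points(bone)
        moved = locate_feature_points(bone.translated(da, ds))
        assert moved.S.a == pytest.approx(pts.S.a + da, abs=1e-9)
        assert moved.I.s == pytest.approx(pts.I.s + ds, abs=1e-9)


class TestDistances:
    def test_rectangle_oracle(self, rectangle_anatomy):
        pts = locate_feature_points(rectangle_anatomy.bone)
        d = measure_distances(rectangle_anatomy, pts)
        assert d.d3 == pytest.approx(30, abs=1e-9)
        assert d.d4 == pytest.approx(15, abs=1e-9)
        assert d.d5 == pytest.approx(32, abs=1e-9)
        assert d.d6 == pytest.approx(15, abs=1e-9)
        assert d.d7 == pytest.approx(0, abs=1e-9)
        assert d.d2 == pytest.approx(45, abs=1e-9)
        assert d.d1 == pytest.approx(math.sqrt(10**2 + 45**2), abs=1e-9)

    def test_rigid_translation_leaves_distances_unchanged(self, rectangle_anatomy):
        pts = locate_feature_points(rectangle_anatomy.bone)
        d0 = measure_distances(rectangle_anatomy, pts).as_array()
        moved = rectangle_anatomy.translated(7.3, -11.9)
        d1 = measure_distances(moved, locate_feature_points(moved.bone)).as_array()
        assert np.max(np.abs(d1 - d0)) < 1e-9

    def test_posterior_widening_changes_only_diameters(self, rectangle_anatomy):
        pts = locate_feature_points(rectangle_anatomy.bone)
        d0 = measure_distances(rectangle_anatomy, pts)
        import dataclasses
        widened = dataclasses.replace(rectangle_anatomy)
        widened.rectum = rectangle(-50, -30, -60, 10)  # +5 mm posterior only
        d1 = measure_distances(widened, pts)
        assert d1.d3 == pytest.approx(d0.d3, abs=1e-9)
        assert d1.d5 == pytest.approx(d0.d5, abs=1e-9)
        assert d1.d4 == pytest.approx(d0.d4 + 5, abs=1e-9)
        assert d1.d6 == pytest.approx(d0.d6 + 5, abs=1e-9)
        assert d1.d7 == pytest.approx(d0.d7, abs=1e-9)

    def test_anterior_wall_approach_decreases_d3(self, rectangle_anatomy):
        pts = locate_feature_points(rectangle_anatomy.bone)
        d0 = measure_distances(rectangle_anatomy, pts)
        import dataclasses
        moved = dataclasses.replace(rectangle_anatomy)
        moved.rectum = rectangle(-45, -27, -60, 10)  # anterior wall 3 mm closer to S
        d1 = measure_distances(moved, pts)
        assert d1.d3 < d0.d3

    def test_missing_intersection_names_the_distance(self, rectangle_anatomy):
        import dataclasses
        broken = dataclasses.replace(rectangle_anatomy)
        broken.rectum = rectangle(-45, -30, 20, 40)  # above both AP lines
        pts = locate_feature_points(broken.bone)
        with pytest.raises(FeatureNotMeasurable, match="d3"):
            measure_distances(broken, pts)

    def test_d7_identity_enforced(self):
        with pytest.raises(ValueError, match="d7"):
            DistanceSet(d1=1, d2=1, d3=1, d4=2, d5=1, d6=5, d7=1)


class TestProstateCenter:
    def test_bounding_box_midpoint(self):
        assert prostate_center(rectangle(-25, -5, -35, -5)).as_tuple() == (-15, -20)

    def test_circle_center(self):
        from ctvshift import superellipse
        c = superellipse(Point2D(3.5, -7.25), 12, 12, 2.0, 128)
        ctr = prostate_center(c)
        assert ctr.a == pytest.approx(3.5, abs=1e-9)
        assert ctr.s == pytest.approx(-7.25, abs=1e-9)

    def test_translation_equivariance(self):
        c = rectangle(-25, -5, -35, -5)
        ctr = prostate_center(c.translated(4, 9))
        assert ctr.as_tuple() == (-11, -11)


class TestFeatureVector:
    def test_identity_pair_is_zero(self):
        d = DistanceSet(d1=46, d2=45, d3=30, d4=15, d5=32, d6=15, d7=0)
        fv = compute_features(d, d, Point2D(-15, -20), Point2D(-15, -20))
        assert np.all(fv.as_array() == 0.0)

    def test_single_distance_difference(self):
        dp = DistanceSet(d1=46, d2=45, d3=30, d4=15, d5=32, d6=15, d7=0)
        dc = DistanceSet(d1=46, d2=45, d3=35, d4=15, d5=32, d6=15, d7=0)
        fv = compute_features(dp, dc, Point2D(0, 0), Point2D(0, 0))
        assert fv.f3 == 5
        assert all(getattr(fv, f"f{i}") == 0 for i in (1, 2, 4, 5, 6, 7, 8, 9))

    @given(st.lists(st.floats(1, 60), min_size=12, max_size=12))
    @settings(max_examples=50, deadline=None)
    def test_f7_identity_exact(self, vals):
        dp = DistanceSet(d1=vals[0], d2=vals[1], d3=vals[2], d4=vals[3],
                         d5=vals[4], d6=vals[5], d7=vals[5] - vals[3])
        dc = DistanceSet(d1=vals[6], d2=vals[7], d3=vals[8], d4=vals[9],
                         d5=vals[10], d6=vals[11], d7=vals[11] - vals[9])
        fv = compute_features(dp, dc, Point2D(0, 0), Point2D(1, 2))
        assert fv.f7 == fv.f6 - fv.f4  # exact, not approximate

    def test_diameter_changes_propagate(self):
        dp = DistanceSet(d1=1, d2=1, d3=1, d4=25, d5=1, d6=20, d7=-5)
        dc = DistanceSet(d1=1, d2=1, d3=1, d4=27, d5=1, d6=24, d7=-3)
        fv = compute_features(dp, dc, Point2D(0, 0), Point2D(0, 0))
        assert fv.f4 == 2 and fv.f6 == 4 and fv.f7 == 2
        assert fv.f7 == fv.f6 - fv.f4
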