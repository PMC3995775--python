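"""Slice geometry: plane construction, projection, signed version angle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from glenvault import (
    DegenerateGeometryError,
    InputError,
    LandmarkSet,
    MissingLandmarkError,
    Plane,
    SlicePoint2D,
    corrected_slice,
    project,
    scapular_plane,
    signed_version_angle,
)
from glenvault.simulate import build_shoulder

from conftest import make_landmarks, random_rigid


class TestLandmarkSet:
    def test_missing_required_landmark_is_named(self):
        bad = dict(make_landmarks().points)
        del bad["posterior_rim"]
        with pytest.raises(MissingLandmarkError, match="posterior_rim"):
            LandmarkSet("X", "right", bad)

    def test_unknown_landmark_rejected(self):
        with pytest.raises(InputError, match="unknown landmark"):
            make_landmarks(acromion=[0, 0, 0])

    def test_collinear_plane_landmarks_rejected(self):
        with pytest.raises(DegenerateGeometryError, match="collinear"):
            make_landmarks(
                inferior_angle=[0, 0, 0],
                glenoid_center=[1, 1, 1],
                medial_point=[2, 2, 2],
            )

    def test_coincident_rims_rejected(self):
        with pytest.raises(DegenerateGeometryError, match="rim"):
            make_landmarks(anterior_rim=[1, 2, 3], posterior_rim=[1, 2, 3])

    def test_non_finite_coordinates_rejected(self):
        with pytest.raises(InputError, match="non-finite"):
            make_landmarks(vault_tip=[np.nan, 0, 0])

    def test_bad_side_and_dominance_rejected(self):
        with pytest.raises(InputError, match="side"):
            make_landmarks(side="superior")
        with pytest.raises(InputError, match="dominance"):
            make_landmarks(dominance="lefty")


class TestScapularPlane:
    def test_simple_triangle_gives_z_normal_and_contains_points(self):
        lm = make_landmarks(
            inferior_angle=[1, 0, 0],
            glenoid_center=[0, 0, 0],
            medial_point=[0, 1, 0],
            anterior_rim=[0.3, 0.2, 1.0],
            posterior_rim=[-0.3, -0.2, -1.0],
            vault_tip=[0.5, 0.5, 0],
            medial_border_tip=[0.1, 1.0, 0],
        )
        plane = scapular_plane(lm)
        assert abs(abs(plane.normal[2]) - 1.0) < 1e-12
        for name in ("inferior_angle", "glenoid_center", "medial_point"):
            assert plane.contains(lm.point(name), tol=1e-9)
        assert np.allclose(plane.origin, lm.point("glenoid_center"))

    @pytest.mark.parametrize("seed", range(5))
    def test_containment_preserved_under_rigid_transform(self, seed):
        rng = np.random.default_rng(seed)
        lm = make_landmarks()
        R, t = random_rigid(rng)
        moved = lm.transformed(R, t)
        plane = scapular_plane(moved)
        for name in ("inferior_angle", "glenoid_center", "medial_point"):
            assert abs(plane.signed_distance(moved.point(name))) < 1e-6


class TestCorrectedSlice:
    def test_orthogonal_construction(self):
        # scapular axis along +x, scapular plane = xy -> slice = xz, u = +x
        lm = make_landmarks(
            glenoid_center=[0, 0, 0],
            medial_point=[-1, 0, 0],
            inferior_angle=[-1, 2, 0],
            anterior_rim=[0.2, 0, 1.0],
            posterior_rim=[-0.2, 0, -1.0],
            vault_tip=[-0.5, 0, 0],
            medial_border_tip=[-1, 0.5, 0],
        )
        slc = corrected_slice(lm)
        assert np.allclose(slc.u_axis, [1, 0, 0], atol=1e-12)
        assert abs(abs(slc.normal[1]) - 1.0) < 1e-12  # xz-plane
        assert np.allclose(slc.v_axis, [0, 0, 1], atol=1e-12)  # toward anterior rim
        assert slc.contains(lm.point("glenoid_center"))
        assert slc.contains(lm.point("medial_point"))

    def test_slice_normal_orthogonal_to_scapular_normal(self):
        lm = make_landmarks()
        scap = scapular_plane(lm)
        slc = corrected_slice(lm, scap)
        assert abs(np.dot(slc.normal, scap.normal)) < 1e-9

    @pytest.mark.parametrize("seed", range(8))
    def test_projected_coordinates_rigid_invariant(self, seed):
        rng = np.random.default_rng(1000 + seed)
        lm, _ = build_shoulder(
            12.0, 6.0, inclination_deg=15.0, shoulder_id="R", side="right"
        )
        before = {n: project(p, corrected_slice(lm)) for n, p in lm.points.items()}
        R, t = random_rigid(rng)
        moved = lm.transformed(R, t)
        after_plane = corrected_slice(moved)
        for name, p2 in before.items():
            q2 = project(moved.point(name), after_plane)
            assert abs(p2.x - q2.x) < 1e-6 and abs(p2.y - q2.y) < 1e-6

    def test_coincident_axis_endpoints_rejected(self):
        lm = make_landmarks()
        lm.points["medial_point"] = lm.points["glenoid_center"].copy()
        with pytest.raises(DegenerateGeometryError, match="coincide"):
            corrected_slice(lm)

    def test_anterior_rim_has_larger_y_than_posterior(self):
        for side in ("right", "left"):
            lm, _ = build_shoulder(20.0, 5.0, side=side, inclination_deg=10.0)
            slc = corrected_slice(lm)
            assert project(lm.point("anterior_rim"), slc).y > project(
                lm.point("posterior_rim"), slc
            ).y


class TestPlaneFrame:
    def test_orthonormality_enforced(self):
        with pytest.raises(DegenerateGeometryError):
            Plane(
                origin=[0, 0, 0], normal=[0, 0, 2.0], u_axis=[1, 0, 0], v_axis=[0, 1, 0]
            )
        with pytest.raises(DegenerateGeometryError):
            Plane(
                origin=[0, 0, 0],
                normal=[0, 0, 1.0],
                u_axis=[1, 0, 0],
                v_axis=[0.6, 0.8, 0],
            )

    def test_left_handed_frame_rejected(self):
        with pytest.raises(DegenerateGeometryError, match="right-handed"):
            Plane(origin=[0, 0, 0], normal=[0, 0, -1.0], u_axis=[1, 0, 0], v_axis=[0, 1, 0])


class TestProject:
    def test_drop_normal_component(self):
        plane = Plane(origin=[0, 0, 0], normal=[0, 0, 1.0], u_axis=[1, 0, 0], v_axis=[0, 1, 0])
        p2 = project([3.0, 4.0, 5.0], plane)
        assert (p2.x, p2.y) == (3.0, 4.0)

    def test_in_plane_round_trip_is_identity(self):
        plane = corrected_slice(make_landmarks())
        p = plane.origin + 3.7 * plane.u_axis - 1.2 * plane.v_axis
        p2 = project(p, plane)
        assert np.linalg.norm(plane.to_world(p2) - p) < 1e-9

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_least_squares_oracle(self, seed):
        rng = np.random.default_rng(seed)
        plane = corrected_slice(make_landmarks())
        point = rng.uniform(-50, 50, 3)
        # brute force: minimize |origin + x u + y v - point|
        A = np.column_stack([plane.u_axis, plane.v_axis])
        xy, *_ = np.linalg.lstsq(A, point - plane.origin, rcond=None)
        p2 = project(point, plane)
        assert abs(p2.x - xy[0]) < 1e-9 and abs(p2.y - xy[1]) < 1e-9


class TestSignedVersionAngle:
    AXIS = (SlicePoint2D(0.0, 0.0), SlicePoint2D(10.0, 0.0))

    @staticmethod
    def rims(theta_deg, mid=(10.0, 0.0), half=14.0):
        """Glenoid line rotated theta from the axis perpendicular; posterior
        rim medial for positive theta (retroversion)."""
        th = math.radians(theta_deg)
        d = np.array([math.sin(th), math.cos(th)])
        m = np.asarray(mid)
        return SlicePoint2D(*(m + half * d)), SlicePoint2D(*(m - half * d))

    def test_perpendicular_line_is_neutral(self):
        ant, post = self.rims(0.0)
        assert signed_version_angle(ant, post, *self.AXIS) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("theta", [1.0, 5.0, 10.0, 22.5, 30.0, 45.0])
    def test_constructed_rotation_recovered(self, theta):
        ant, post = self.rims(theta)
        got = signed_version_angle(ant, post, *self.AXIS)
        assert got == pytest.approx(theta, abs=1e-9)

    @pytest.mark.parametrize("theta", [1.0, 10.0, 45.0])
    def test_mirror_turns_retroversion_into_anteversion(self, theta):
        # reflect across the axis perpendicular through the line midpoint:
        # the posterior rim moves from medial to lateral, flipping the sign
        ant, post = self.rims(theta)
        m_ant = SlicePoint2D(20.0 - ant.x, ant.y)
        m_post = SlicePoint2D(20.0 - post.x, post.y)
        got = signed_version_angle(m_ant, m_post, *self.AXIS)
        assert got == pytest.approx(-theta, abs=1e-9)

    @pytest.mark.parametrize("theta", [1.0, 10.0, 45.0])
    def test_reflection_across_the_axis_line_preserves_version(self, theta):
        # a shoulder seen in a mirror across its own axis keeps its version
        ant, post = self.rims(theta)
        m_ant = SlicePoint2D(ant.x, -ant.y)
        m_post = SlicePoint2D(post.x, -post.y)
        got = signed_version_angle(m_ant, m_post, *self.AXIS)
        assert got == pytest.approx(theta, abs=1e-9)

    def test_swapping_rim_labels_negates(self):
        ant, post = self.rims(17.0)
        assert signed_version_angle(post, ant, *self.AXIS) == pytest.approx(-17.0, abs=1e-9)

    def test_reversing_axis_direction_negates(self):
        # the sign is anchored to the medial->lateral axis direction
        ant, post = self.rims(8.0)
        a = signed_version_angle(ant, post, *self.AXIS)
        b = signed_version_angle(ant, post, self.AXIS[1], self.AXIS[0])
        assert b == pytest.approx(-a, abs=1e-9)

    def test_degenerate_inputs_raise(self):
        p = SlicePoint2D(1.0, 1.0)
        with pytest.raises(DegenerateGeometryError, match="glenoid line"):
            signed_version_angle(p, p, *self.AXIS)
        ant, post = self.rims(5.0)
        with pytest.raises(DegenerateGeometryError, match="axis"):
            signed_version_angle(ant, post, p, p)


@settings(max_examples=30, deadline=None)
@given(
    vault=st.floats(-20, 60),
    offset=st.floats(-15, 15),
    scale=st.floats(0.2, 5.0),
)
def test_angles_scale_invariant(vault, offset, scale):
    """Uniform scaling of all landmarks leaves both version angles unchanged."""
    from glenvault import conventional_version, vault_version

    lm, _ = build_shoulder(vault, offset, inclination_deg=12.0)
    scaled = lm.transformed(scale=scale)
    assert vault_version(scaled).version_deg == pytest.approx(
        vault_version(lm).version_deg, abs=1e-9
    )
    assert conventional_version(scaled).version_deg == pytest.approx(
        conventional_version(lm).version_deg, abs=1e-9
    )
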