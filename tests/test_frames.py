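"""Coordinate conventions, Cardan composition and cup-axis geometry."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hipimpinge.frames import (
    CupOrientation,
    GimbalLockError,
    JointAngles,
    RigidTransform,
    cup_axis,
    cup_orientation_from_axis,
    joint_angles_from_rotation,
    mirror_z,
    rotation_from_joint_angles,
)


def rot_about(axis, deg):
    """Independent axis-angle rotation (Rodrigues), for oracle composition."""
    axis = np.asarray(axis, float) / np.linalg.norm(axis)
    t = np.radians(deg)
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(t) * k + (1 - np.cos(t)) * (k @ k)


class TestRigidTransform:
    def test_rotation_validated(self):
        with pytest.raises(ValueError, match="orthonormal"):
            RigidTransform(np.eye(3) * 2.0)
        with pytest.raises(ValueError, match="reflection"):
            RigidTransform(np.diag([1.0, 1.0, -1.0]))
        with pytest.raises(ValueError, match="finite"):
            RigidTransform(np.full((3, 3), np.nan))

    def test_compose_inverse_identity(self, rng):
        transforms = [
            rotation_from_joint_angles(
                JointAngles(*rng.uniform(-170, 170, 3) * [1, 0.45, 1])
            )
            @ RigidTransform.from_translation(rng.normal(size=3))
            for _ in range(20)
        ]
        for t in transforms:
            round_trip = t @ t.inverse()
            assert np.allclose(round_trip.rotation, np.eye(3), atol=1e-9)
            assert np.allclose(round_trip.translation, 0.0, atol=1e-9)
        a, b, c = transforms[:3]
        left = (a @ b) @ c
        right = a @ (b @ c)
        assert np.allclose(left.rotation, right.rotation, atol=1e-12)
        assert np.allclose(left.translation, right.translation, atol=1e-9)


class TestJointRotation:
    def test_neutral_is_identity(self):
        t = rotation_from_joint_angles(JointAngles(0, 0, 0))
        assert np.allclose(t.rotation, np.eye(3))
        assert np.allclose(t.translation, 0.0)

    def test_flexion_90_sends_shaft_anterior(self):
        t = rotation_from_joint_angles(JointAngles(90, 0, 0))
        assert np.allclose(t.apply_vector([0, -1, 0]), [1, 0, 0], atol=1e-12)

    def test_adduction_90_sends_shaft_medial(self):
        t = rotation_from_joint_angles(JointAngles(0, 90, 0))
        assert np.allclose(t.apply_vector([0, -1, 0]), [0, 0, -1], atol=1e-12)

    def test_internal_rotation_fixes_shaft(self):
        t = rotation_from_joint_angles(JointAngles(0, 0, 37.5))
        assert np.allclose(t.apply_vector([0, -1, 0]), [0, -1, 0], atol=1e-12)

    def test_matches_axis_angle_oracle(self):
        """Sequence contract: flexion about Z, then adduction about the
        rotated X, then internal rotation about the rotated shaft axis."""
        f, a, r = 30.0, 10.0, -15.0
        rz = rot_about([0, 0, 1], f)
        rx = rot_about(rz @ [1, 0, 0], a)
        ry = rot_about(rx @ rz @ [0, 1, 0], r)
        expected = ry @ rx @ rz
        got = rotation_from_joint_angles(JointAngles(f, a, r)).rotation
        assert np.abs(got - expected).max() < 1e-9

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            JointAngles(np.nan, 0, 0)
        with pytest.raises(ValueError):
            JointAngles(0, 200.0, 0)

    def test_round_trip_sweep_within_hundredth_degree(self, rng):
        """Angle read-back over a dense commanded grid: the verification
        bound for the whole kinematic chain is 0.01 deg."""
        worst = 0.0
        for _ in range(1000):
            angles = JointAngles(
                rng.uniform(-179, 179),
                rng.uniform(-80, 80),
                rng.uniform(-179, 179),
            )
            back = joint_angles_from_rotation(rotation_from_joint_angles(angles))
            worst = max(worst, np.abs(back.as_array() - angles.as_array()).max())
        assert worst <= 0.01

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(
        flexion=st.floats(-179.0, 179.0),
        adduction=st.floats(-80.0, 80.0),
        rotation=st.floats(-179.0, 179.0),
    )
    def test_round_trip_property(self, flexion, adduction, rotation):
        """Any reachable angle triple away from gimbal lock survives the
        angles -> rotation -> angles round trip."""
        angles = JointAngles(flexion, adduction, rotation)
        back = joint_angles_from_rotation(rotation_from_joint_angles(angles))
        assert np.abs(back.as_array() - angles.as_array()).max() <= 0.01

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(inc=st.floats(1.0, 89.0), av=st.floats(-89.0, 89.0))
    def test_cup_axis_injective_property(self, inc, av):
        """The opening-axis map is invertible on the open orientation range."""
        o = cup_orientation_from_axis(cup_axis(CupOrientation(inc, av)))
        assert abs(o.inclination - inc) <= 1e-9
        assert abs(o.anteversion - av) <= 1e-9

    def test_gimbal_lock_flagged(self):
        t = rotation_from_joint_angles(JointAngles(25.0, 90.0, 0.0))
        with pytest.raises(GimbalLockError):
            joint_angles_from_rotation(t)


class TestCupAxis:
    def test_neutral_opening_points_inferior(self):
        assert np.allclose(cup_axis(CupOrientation(0, 0)), [0, -1, 0])

    def test_inclination_90_opening_points_lateral(self):
        assert np.allclose(
            cup_axis(CupOrientation(90, 0)), [0, 0, 1], atol=1e-12
        )

    def test_definition_inverts(self):
        """Anteversion is the angle out of the coronal plane; inclination the
        coronal-projection angle from inferior."""
        n = cup_axis(CupOrientation(45, 20))
        assert np.isclose(n[0], np.sin(np.radians(20)))
        proj = np.array([0.0, n[1], n[2]])
        proj /= np.linalg.norm(proj)
        assert np.isclose(np.degrees(np.arccos(proj @ [0, -1, 0])), 45.0)

    @pytest.mark.parametrize("inc,av", [(10, -40), (45, 20), (80, 5), (30, 0)])
    def test_axis_recovery_exact(self, inc, av):
        o = cup_orientation_from_axis(cup_axis(CupOrientation(inc, av)))
        assert abs(o.inclination - inc) < 1e-9
        assert abs(o.anteversion - av) < 1e-9

    def test_left_side_mirrors_lateral(self):
        r = cup_axis(CupOrientation(45, 20, side="right"))
        l = cup_axis(CupOrientation(45, 20, side="left"))
        assert np.allclose(l, mirror_z(r))

    def test_orientation_validated(self):
        with pytest.raises(ValueError):
            CupOrientation(100, 0)
        with pytest.raises(ValueError):
            CupOrientation(45, 95)
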