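"""Detection, first-impingement bisection, and rim localisation."""
import numpy as np
import pytest

from hipimpinge import (
    CupOrientation,
    ImplantSpec,
    JointAngles,
    build_scene,
    detect,
    first_impingement,
    oscillation_half_angle,
    rim_location,
    synthesize,
)
from hipimpinge.kinematics import ActivityTemplate
from hipimpinge.placement import StemAngles


def flexion_ramp(peak, n=49):
    return synthesize(
        ActivityTemplate("ramp", peak, 0.0, 0.0, phase_offsets=(0, 0, 0), n_samples=n)
    )


class TestDetect:
    def test_neutral_pose_clear(self, default_scene):
        assert detect(default_scene, JointAngles(0, 0, 0)).kind == "none"

    def test_flexion_beyond_oscillation_angle_is_component(self, straight_neck_scene):
        osc = 80.0
        res = detect(
            straight_neck_scene, JointAngles(osc + 2.0, 0, 0), threshold=0.02
        )
        assert res.kind == "component"
        assert res.component_volume > 0.02

    def test_flexion_below_oscillation_angle_clear(self, straight_neck_scene):
        res = detect(straight_neck_scene, JointAngles(77.0, 0, 0), threshold=0.02)
        assert res.kind == "none"

    def test_deep_external_rotation_is_bone(self, default_scene):
        """Posterior osseous neck against the ischium at extreme external
        rotation, with the components still clear."""
        res = detect(default_scene, JointAngles(0, 0, -88.0))
        assert res.kind == "bone"

    def test_threshold_validated(self, default_scene):
        with pytest.raises(ValueError):
            detect(default_scene, JointAngles(0, 0, 0), threshold=0.0)


class TestFirstImpingement:
    def test_zero_peak_trajectory_clear(self, default_scene):
        traj = synthesize(ActivityTemplate("NIL", 0.0, 0.0, 0.0))
        assert first_impingement(default_scene, traj) is None

    def test_pure_flexion_contact_matches_analytic_oscillation(
        self, straight_neck_scene
    ):
        """Mesh pipeline vs closed form: straight 10 deg cone neck in a
        hemispherical liner opening inferiorly -> contact at 80 deg."""
        event = first_impingement(
            straight_neck_scene, flexion_ramp(120.0), threshold=0.02
        )
        assert event is not None and event.kind == "component"
        assert event.angles_at_contact.flexion == pytest.approx(80.0, abs=0.5)
        assert event.angles_at_contact.adduction == 0.0

    def test_bisection_respects_tolerance(self, straight_neck_scene):
        """A coarser trajectory still localises contact to the bisection
        tolerance, not the sample spacing."""
        coarse = first_impingement(
            straight_neck_scene, flexion_ramp(120.0, n=17), threshold=0.02,
            tolerance_deg=0.1,
        )
        fine = first_impingement(
            straight_neck_scene, flexion_ramp(120.0, n=97), threshold=0.02,
            tolerance_deg=0.1,
        )
        assert abs(
            coarse.angles_at_contact.flexion - fine.angles_at_contact.flexion
        ) <= 0.3

    def test_monotone_ramp_detection_is_monotone(self, straight_neck_scene):
        """Along a single-axis ramp, every configuration past first contact
        also detects."""
        event = first_impingement(
            straight_neck_scene, flexion_ramp(120.0), threshold=0.02
        )
        f0 = event.angles_at_contact.flexion
        for f in np.linspace(f0 + 0.5, 120.0, 6):
            assert detect(
                straight_neck_scene, JointAngles(f, 0, 0), threshold=0.02
            ).any, f

    def test_neutral_impingement_warns(self, straight_neck_scene):
        """A trajectory that starts beyond contact reports fraction 0 with a
        warning rather than failing."""
        bad = synthesize(
            ActivityTemplate("BAD", 90.0, 0.0, 0.0, phase_offsets=(0, 0, 0))
        )
        shifted = type(bad)(
            name="BAD", times=bad.times, angles=bad.angles + [85.0, 0.0, 0.0]
        )
        with pytest.warns(UserWarning, match="neutral"):
            event = first_impingement(straight_neck_scene, shifted, threshold=0.02)
        assert event.trajectory_fraction == 0.0
        assert event.neutral_impingement

    def test_event_serialises(self, straight_neck_scene):
        event = first_impingement(
            straight_neck_scene, flexion_ramp(120.0), threshold=0.02
        )
        d = event.to_dict()
        assert d["kind"] == "component"
        assert 0 < d["trajectory_fraction"] < 1
        assert d["rim_location_bucketed_deg"] % 5 == 0


class TestRimLocation:
    def test_anterior_flexion_contact_near_90(self, straight_neck_scene):
        """With the cup opening inferior, pure flexion carries the neck
        anteriorly: contact sits at the anterior mark of the rim clock."""
        theta = rim_location(
            straight_neck_scene, JointAngles(81.5, 0, 0), threshold=0.02
        )
        assert theta == pytest.approx(90.0, abs=5.0)

    def test_mirrored_motion_reflects_about_superior_axis(self):
        """Sign-flipping adduction and rotation mirrors the motion through
        the sagittal plane; in a laterally symmetric scene the rim azimuth
        reflects about the 0-180 axis."""
        spec = ImplantSpec(neck_shaft_angle=180.0, neck_cone_half_angle=10.0)
        # lateral symmetry needs the cup axis in the sagittal plane, which
        # means zero inclination; anteversion keeps the azimuth origin
        # (projected superior) well defined
        scene = build_scene(
            implant_spec=spec,
            cup=CupOrientation(0.0, 20.0),
            stem=StemAngles(0.0, 0.0, 6.0),
            include_bones=False,
        )
        angles = JointAngles(97.0, 18.0, 25.0)
        mirrored = JointAngles(97.0, -18.0, -25.0)
        t1 = rim_location(scene, angles, threshold=0.02)
        t2 = rim_location(scene, mirrored, threshold=0.02)
        assert t1 is not None and t2 is not None
        assert abs(((t1 + t2) % 360.0)) == pytest.approx(0.0, abs=2.0) or (
            abs(((t1 + t2) % 360.0) - 360.0) < 2.0
        )

    def test_no_interference_returns_none(self, straight_neck_scene):
        assert rim_location(straight_neck_scene, JointAngles(10, 0, 0)) is None
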