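"""First impingement during one activity at one cup orientation.

Implants the default construct (36 mm head, 56 mm shell, surrogate bones),
places the cup at 30 degrees inclination / 0 anteversion — a low-anteversion
position known to be at risk during deep flexion — and runs the STOOP
activity (standing bend to the floor).
"""
from hipimpinge import CupOrientation, build_scene, first_impingement, synthesize
from hipimpinge.kinematics import DEFAULT_TEMPLATES

scene = build_scene(cup=CupOrientation(inclination=30.0, anteversion=0.0))
trajectory = synthesize(DEFAULT_TEMPLATES["STOOP"])

event = first_impingement(scene, trajectory)
if event is None:
    print("no impingement during STOOP at 30/0")
else:
    a = event.angles_at_contact
    print(f"impingement type    : {event.kind}")
    print(f"joint angles        : flexion {a.flexion:.1f}, adduction {a.adduction:.1f}, "
          f"rotation {a.rotation:.1f} deg")
    print(f"trajectory fraction : {event.trajectory_fraction:.3f}")
    print(f"rim location        : {event.rim_location:.1f} deg clockwise from superior")
    print(f"                      (bucketed: {event.rim_location_bucketed:.0f} deg)")
    print(f"interference volume : {event.interference_volume:.2f} mm^3")
    print("\nA rim location between 0 and 90 deg is the antero-superior")
    print("quadrant: prosthetic neck on liner rim during deep flexion, the")
    print("mechanism behind posterior dislocation.")
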