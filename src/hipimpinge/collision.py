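"""Interference detection, first-impingement search, and rim localisation.

An impingement event is the first configuration along a time-ordered joint
trajectory at which the interference volume between opposing solids exceeds a
threshold (default 1 mm^3).  Component impingement is any femoral implant mesh
against any acetabular implant mesh; bone impingement is femur against pelvis.
The trajectory is scanned sample by sample; the first super-threshold sample
is refined by bisection (linear interpolation of each joint axis) until the
bracket on the largest-moving axis is below an angular tolerance, and the
event is reported at the first super-threshold configuration found.

For component events the contact is localised on the liner rim as an azimuth
in the rim plane, measured clockwise from the projection of pelvic superior
(+Y) when viewing the cup face from lateral: superior 0, anterior 90,
inferior 180, posterior 270 degrees (right hip).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .frames import JointAngles, RigidTransform
from .kinematics import Trajectory
from .mesh import interference_samples, interference_volume
from .placement import ImplantedScene

__all__ = [
    "DetectionResult",
    "ImpingementEvent",
    "detect",
    "first_impingement",
    "rim_location",
    "interference_volume",
]

DEFAULT_VOLUME_THRESHOLD = 1.0  # mm^3
DEFAULT_BISECTION_TOL = 0.1  # deg on the largest-moving axis
RIM_REPORT_BUCKET = 5.0  # deg granularity for reported rim locations


@dataclass(frozen=True)
class DetectionResult:
    """Outcome of interference detection at one joint configuration."""

    kind: str  # none | component | bone | component_and_bone
    component_volume: float
    bone_volume: float

    @property
    def any(self) -> bool:
        return self.kind != "none"


@dataclass(frozen=True)
class ImpingementEvent:
    """First contact along a trajectory."""

    kind: str  # component | bone | component_and_bone
    angles_at_contact: JointAngles
    trajectory_fraction: float
    interference_volume: float
    rim_location: float | None = None  # deg cw from superior; component only
    neutral_impingement: bool = False

    @property
    def rim_location_bucketed(self) -> float | None:
        if self.rim_location is None:
            return None
        return (round(self.rim_location / RIM_REPORT_BUCKET) * RIM_REPORT_BUCKET) % 360.0

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "angles_at_contact": self.angles_at_contact.as_dict(),
            "trajectory_fraction": self.trajectory_fraction,
            "interference_volume_mm3": self.interference_volume,
            "rim_location_deg": self.rim_location,
            "rim_location_bucketed_deg": self.rim_location_bucketed,
            "neutral_impingement": self.neutral_impingement,
        }


def _pair_volume(
    scene: ImplantedScene,
    fem_label: str,
    pel_label: str,
    angles: JointAngles,
) -> float:
    """Interference volume of one femoral/pelvic mesh pair at given angles,
    with cheap broad/mid-phase rejection."""
    fem = scene.femoral_side_meshes[fem_label]
    pel = scene.pelvic_side_meshes[pel_label]
    pose_f = scene.femoral_world_pose(fem_label, angles)
    pose_p = pel.pose

    ca, ra = fem.surface.bounding_sphere
    cb, rb = pel.surface.bounding_sphere
    if np.linalg.norm(pose_f.apply(ca) - pose_p.apply(cb)) > ra + rb:
        return 0.0
    # mid phase: if every proxy point of the femoral surface clears the pelvic
    # solid by more than the proxy covering radius, the surfaces cannot cross;
    # one containment probe rules out the pelvic mesh sitting wholly inside
    proxies, cover = fem.surface.proxy_points
    to_p = pose_p.inverse() @ pose_f
    if pel.surface.signed_distance(to_p.apply(proxies)).min() > cover:
        to_f = pose_f.inverse() @ pose_p
        probe = to_f.apply(pel.surface.vertices[:1])
        if fem.surface.signed_distance(probe)[0] > 0:
            return 0.0
    return interference_volume(fem.surface, pel.surface, pose_f, pose_p)


def detect(
    scene: ImplantedScene,
    angles: JointAngles,
    threshold: float = DEFAULT_VOLUME_THRESHOLD,
) -> DetectionResult:
    """Classify interference at one joint configuration.

    ``component`` when any femoral implant mesh interferes with any acetabular
    implant mesh by more than ``threshold`` mm^3; ``bone`` likewise for femur
    vs pelvis; both categories together give ``component_and_bone``.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    comp = sum(
        _pair_volume(scene, f, p, angles) for f, p in scene.component_pairs()
    )
    bone = sum(
        _pair_volume(scene, f, p, angles) for f, p in scene.bone_pairs()
    )
    kinds = {(True, True): "component_and_bone", (True, False): "component",
             (False, True): "bone", (False, False): "none"}
    return DetectionResult(
        kind=kinds[(comp > threshold, bone > threshold)],
        component_volume=float(comp),
        bone_volume=float(bone),
    )


def first_impingement(
    scene: ImplantedScene,
    trajectory: Trajectory,
    tolerance_deg: float = DEFAULT_BISECTION_TOL,
    threshold: float = DEFAULT_VOLUME_THRESHOLD,
) -> ImpingementEvent | None:
    """First super-threshold interference along a trajectory, or None.

    Samples are scanned in time order; the first detecting sample is bracketed
    against its predecessor and bisected (each axis linearly interpolated)
    until the largest-moving axis moves less than ``tolerance_deg`` across the
    bracket.  The event is evaluated at the detecting end of the final
    bracket, so the reported configuration is the first known super-threshold
    one.
    """
    if tolerance_deg <= 0:
        raise ValueError("tolerance_deg must be > 0")
    fractions = trajectory.fractions
    hit_idx = None
    for i in range(len(fractions)):
        res = detect(scene, trajectory.joint_angles(i), threshold)
        if res.any:
            hit_idx = i
            break
    if hit_idx is None:
        return None
    if hit_idx == 0:
        warnings.warn(
            f"{trajectory.name}: impingement already present at the neutral "
            "start of the trajectory",
            stacklevel=2,
        )
        return _make_event(
            scene, trajectory.joint_angles(0), 0.0, res, threshold, neutral=True
        )

    lo, hi = fractions[hit_idx - 1], fractions[hit_idx]
    hi_res = res
    span0 = np.abs(
        trajectory.interpolate(hi).as_array() - trajectory.interpolate(lo).as_array()
    ).max()
    while (
        np.abs(
            trajectory.interpolate(hi).as_array()
            - trajectory.interpolate(lo).as_array()
        ).max()
        > tolerance_deg
        and span0 > 0
    ):
        mid = 0.5 * (lo + hi)
        mid_res = detect(scene, trajectory.interpolate(mid), threshold)
        if mid_res.any:
            hi, hi_res = mid, mid_res
        else:
            lo = mid
    return _make_event(scene, trajectory.interpolate(hi), hi, hi_res, threshold)


def _make_event(
    scene: ImplantedScene,
    angles: JointAngles,
    fraction: float,
    res: DetectionResult,
    threshold: float,
    neutral: bool = False,
) -> ImpingementEvent:
    rim = None
    if "component" in res.kind:
        rim = rim_location(scene, angles, threshold)
    return ImpingementEvent(
        kind=res.kind,
        angles_at_contact=angles,
        trajectory_fraction=float(fraction),
        interference_volume=res.component_volume + res.bone_volume,
        rim_location=rim,
        neutral_impingement=neutral,
    )


def rim_location(
    scene: ImplantedScene,
    angles: JointAngles,
    threshold: float = DEFAULT_VOLUME_THRESHOLD,
) -> float | None:
    """Azimuth on the liner rim of the component contact patch centroid.

    Degrees clockwise from the projection of pelvic superior (+Y) onto the rim
    plane, viewed from lateral (right hip): anterior is 90, inferior 180,
    posterior 270.  None when there is no component interference.
    """
    # contact patch: weighted sample points of the neck/liner intersection
    pts_all, w_all = [], []
    for f_label, p_label in scene.component_pairs():
        fem = scene.femoral_side_meshes[f_label]
        pel = scene.pelvic_side_meshes[p_label]
        pts, w, _ = interference_samples(
            fem.surface,
            pel.surface,
            scene.femoral_world_pose(f_label, angles),
            pel.pose,
        )
        if len(pts):
            pts_all.append(pts)
            w_all.append(w)
    if not pts_all:
        return None
    pts = np.concatenate(pts_all)
    w = np.concatenate(w_all)
    centroid = (pts * w[:, None]).sum(axis=0) / w.sum()

    n = scene.cup_opening_axis
    centre = scene.cup_centre
    sup = np.array([0.0, 1.0, 0.0])
    ant = np.array([1.0, 0.0, 0.0])
    u = sup - (sup @ n) * n
    offset = 0.0
    if np.linalg.norm(u) < 1e-6:
        # cup axis (anti)parallel to superior: anchor the scale at anterior=90
        u = ant - (ant @ n) * n
        offset = 90.0
    u = u / np.linalg.norm(u)
    v = np.cross(n, u)
    ref = ant if offset == 0.0 else np.array([0.0, 0.0, -1.0])
    ref_ip = ref - (ref @ n) * n
    if np.linalg.norm(ref_ip) > 1e-6 and ref_ip @ v < 0:
        v = -v
    rel = centroid - centre
    theta = offset + np.degrees(np.arctan2(rel @ v, rel @ u))
    return float(theta % 360.0)
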