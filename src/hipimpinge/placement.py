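"""Virtual implantation: component poses from surgical parameters.

Builds an :class:`ImplantedScene` from an implant specification, bone
surrogates (or loaded meshes), a radiographic cup orientation and stem
orientation angles.  Placement only assigns rigid poses — the underlying
meshes are shared, never mutated — so sweeping cup orientation re-places the
acetabular components and reuses everything else, including cached
signed-distance fields.

The hip COR is the origin of the scene unless a different ``cor`` is given.
In concentric mode (the default) head centre, cup centre and COR coincide;
contact mode translates the head by the radial clearance minus a 1 um gap so
the head rests on the liner without interfering at neutral.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import trimesh

from .anatomy import SurrogateAnatomySpec, build_femur_surrogate, build_pelvis_surrogate
from .frames import (
    CupOrientation,
    JointAngles,
    RigidTransform,
    cup_axis,
    rotation_from_joint_angles,
)
from .implant import ImplantSpec, build_components
from .mesh import MeshSurface

__all__ = [
    "StemAngles",
    "PosedMesh",
    "ImplantedScene",
    "place_cup",
    "place_stem",
    "set_head_mode",
    "build_scene",
    "medial_superior_direction",
]

_CONTACT_GAP = 1e-3  # mm residual gap in head-contact mode


@dataclass(frozen=True)
class StemAngles:
    """Stem orientation: anteversion about the shaft, adduction, flexion (deg)."""

    anteversion: float = 15.0
    adduction: float = 6.0
    flexion: float = 6.0


@dataclass(frozen=True)
class PosedMesh:
    surface: MeshSurface
    pose: RigidTransform


def medial_superior_direction(side: str = "right") -> np.ndarray:
    """Unit vector bisecting medial and superior in the coronal plane."""
    z = -1.0 if side == "right" else 1.0
    return np.array([0.0, 1.0, z]) / math.sqrt(2.0)


def place_cup(
    orientation: CupOrientation,
    cor: np.ndarray | None = None,
    medialise: float = 0.0,
    direction: np.ndarray | None = None,
) -> RigidTransform:
    """Pose of the acetabular components (liner/shell local +Z -> opening axis).

    ``medialise`` translates the cup centre along ``direction`` (default the
    medial-superior bisector) from the COR, emulating deepened reaming.
    """
    if medialise < 0:
        raise ValueError("medialise must be >= 0")
    cor = np.zeros(3) if cor is None else np.asarray(cor, dtype=float)
    n = cup_axis(orientation)
    rot = trimesh.geometry.align_vectors([0.0, 0.0, 1.0], n)[:3, :3]
    if direction is None:
        direction = medial_superior_direction(orientation.side)
    else:
        direction = np.asarray(direction, dtype=float)
        direction = direction / np.linalg.norm(direction)
    return RigidTransform(rot, cor + medialise * direction)


def place_stem(
    anteversion: float = 15.0, adduction: float = 6.0, flexion: float = 6.0
) -> RigidTransform:
    """Pose of the femoral stem (neck) in the neutral femoral frame.

    The neck axis is rotated from its neutral direction by the same Cardan
    sequence as joint motion, with stem anteversion acting as the internal
    rotation term.  Defaults restore a typical conforming implantation.
    """
    for v in (anteversion, adduction, flexion):
        if not math.isfinite(v):
            raise ValueError("stem angles must be finite")
    return rotation_from_joint_angles(JointAngles(flexion, adduction, anteversion))


@dataclass(frozen=True)
class ImplantedScene:
    """All meshes of one virtually implanted hip with their neutral poses.

    Pelvic-side poses are fixed in the pelvic (world) frame; femoral-side
    poses are the components' poses in the neutral femoral frame — at joint
    angles theta the world pose is ``J(theta) o pose`` with J the joint
    rotation about the COR.
    """

    implant_spec: ImplantSpec
    cup: CupOrientation
    stem: StemAngles
    pelvic_side_meshes: dict = field(default_factory=dict)
    femoral_side_meshes: dict = field(default_factory=dict)
    cor: np.ndarray = field(default_factory=lambda: np.zeros(3))
    head_centre_offset: np.ndarray = field(default_factory=lambda: np.zeros(3))
    medialise: float = 0.0
    check_bearing_pair: bool = False

    @property
    def cup_opening_axis(self) -> np.ndarray:
        return cup_axis(self.cup)

    @property
    def cup_centre(self) -> np.ndarray:
        return self.pelvic_side_meshes["liner"].pose.translation

    def joint_transform(self, angles: JointAngles) -> RigidTransform:
        """World transform of the femoral side at the given joint angles
        (rotation about the COR)."""
        rot = rotation_from_joint_angles(angles)
        return RigidTransform(
            rot.rotation, self.cor - rot.rotation @ self.cor
        )

    def femoral_world_pose(self, label: str, angles: JointAngles) -> RigidTransform:
        return self.joint_transform(angles) @ self.femoral_side_meshes[label].pose

    def component_pairs(self) -> list[tuple[str, str]]:
        """Femoral-implant vs acetabular-implant mesh pairs to check.

        The articulating head-liner couple is excluded by default: with the
        head retained in the liner it is in permanent designed near-contact
        and its interference is identically zero.
        """
        fem = [l for l in ("head", "neck") if l in self.femoral_side_meshes]
        pel = [l for l in ("liner", "shell") if l in self.pelvic_side_meshes]
        pairs = [(f, p) for f in fem for p in pel]
        if not self.check_bearing_pair:
            pairs = [p for p in pairs if p != ("head", "liner")]
        return pairs

    def bone_pairs(self) -> list[tuple[str, str]]:
        if "femur" in self.femoral_side_meshes and "pelvis" in self.pelvic_side_meshes:
            return [("femur", "pelvis")]
        return []

    def with_cup(self, orientation: CupOrientation) -> "ImplantedScene":
        """Re-place only the acetabular components at a new orientation."""
        pose = place_cup(orientation, self.cor, self.medialise)
        pelvic = dict(self.pelvic_side_meshes)
        for label in ("liner", "shell"):
            if label in pelvic:
                pelvic[label] = PosedMesh(pelvic[label].surface, pose)
        return replace(self, cup=orientation, pelvic_side_meshes=pelvic)

    def export(self, directory) -> dict:
        """Write every mesh as STL plus a JSON-able pose manifest."""
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = {}
        for group, side in (
            (self.pelvic_side_meshes, "pelvic"),
            (self.femoral_side_meshes, "femoral"),
        ):
            for label, pm in group.items():
                path = directory / f"{label}.stl"
                posed = pm.surface.mesh.copy()
                posed.apply_transform(_to_matrix(pm.pose))
                posed.export(path)
                manifest[label] = {
                    "side": side,
                    "file": path.name,
                    "rotation": pm.pose.rotation.tolist(),
                    "translation": pm.pose.translation.tolist(),
                }
        return manifest


def _to_matrix(pose: RigidTransform) -> np.ndarray:
    m = np.eye(4)
    m[:3, :3] = pose.rotation
    m[:3, 3] = pose.translation
    return m


def set_head_mode(
    scene: ImplantedScene, mode: str, direction: np.ndarray | None = None
) -> ImplantedScene:
    """Switch between concentric and head-on-liner contact positioning.

    ``concentric`` zeroes the head-centre offset; ``contact`` translates the
    head along ``direction`` (default medial-superior) by the radial clearance
    minus a fixed 1 um residual gap.
    """
    if mode not in ("concentric", "contact"):
        raise ValueError("mode must be 'concentric' or 'contact'")
    if mode == "concentric":
        offset = np.zeros(3)
    else:
        if direction is None:
            direction = medial_superior_direction(scene.cup.side)
        else:
            direction = np.asarray(direction, dtype=float)
            direction = direction / np.linalg.norm(direction)
        offset = (scene.implant_spec.clearance - _CONTACT_GAP) * direction
    femoral = dict(scene.femoral_side_meshes)
    head = femoral["head"]
    femoral["head"] = PosedMesh(
        head.surface, RigidTransform(np.eye(3), scene.cor + offset)
    )
    return replace(scene, femoral_side_meshes=femoral, head_centre_offset=offset)


def build_scene(
    implant_spec: ImplantSpec | None = None,
    anatomy_spec: SurrogateAnatomySpec | None = None,
    cup: CupOrientation | None = None,
    stem: StemAngles | None = None,
    medialise: float = 0.0,
    head_mode: str = "concentric",
    include_bones: bool = True,
    components: dict | None = None,
    pelvis: MeshSurface | None = None,
    femur: MeshSurface | None = None,
) -> ImplantedScene:
    """Assemble a full implanted scene.

    Pre-built component meshes / bone surfaces may be passed to share geometry
    (and SDF caches) across scenes; otherwise they are built from the specs.
    The femoral collar of the surrogate femur is aligned with the prosthetic
    neck, reflecting a stem implanted to conform with the native neck.
    """
    implant_spec = implant_spec or ImplantSpec()
    cup = cup or CupOrientation(45.0, 20.0)
    stem = stem or StemAngles()
    if components is None:
        components = build_components(implant_spec)

    cup_pose = place_cup(cup, medialise=medialise)
    stem_rot = place_stem(stem.anteversion, stem.adduction, stem.flexion)
    # neck mesh local axis is +Z; neutral neck direction comes from the spec
    neck_align = RigidTransform(
        trimesh.geometry.align_vectors([0.0, 0.0, 1.0], implant_spec.neck_axis_neutral)[
            :3, :3
        ]
    )

    pelvic = {
        "liner": PosedMesh(components["liner"], cup_pose),
        "shell": PosedMesh(components["shell"], cup_pose),
    }
    femoral = {
        "head": PosedMesh(components["head"], RigidTransform.identity()),
        "neck": PosedMesh(components["neck"], stem_rot @ neck_align),
    }
    if include_bones:
        anatomy_spec = anatomy_spec or SurrogateAnatomySpec()
        if pelvis is None:
            pelvis = build_pelvis_surrogate(anatomy_spec)
        if femur is None:
            femur = build_femur_surrogate(anatomy_spec)
        pelvic["pelvis"] = PosedMesh(pelvis, RigidTransform.identity())
        # collar co-axial with the prosthetic neck
        femoral["femur"] = PosedMesh(femur, stem_rot)
    scene = ImplantedScene(
        implant_spec=implant_spec,
        cup=cup,
        stem=stem,
        pelvic_side_meshes=pelvic,
        femoral_side_meshes=femoral,
        medialise=medialise,
    )
    if head_mode != "concentric":
        scene = set_head_mode(scene, head_mode)
    return scene
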