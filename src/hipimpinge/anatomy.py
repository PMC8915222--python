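"""Surrogate pelvis and femur surface meshes, and readers for real ones.

The surrogates are deliberately schematic compositions of spheres, shells and
capsules — not statistical shape models.  They provide the bony features that
matter for impingement testing:

* pelvis: a thick hemispherical acetabular wall (cavity centred at the hip
  COR, opening along a typical native acetabular direction) plus two spherical
  prominences standing in for the anterior-inferior iliac spine (AIIS,
  anterior-superior to the joint) and the ischium (posterior-inferior);
* femur: the osseous femoral neck as a cylindrical collar around the
  prosthetic neck region (the natural head is resected) joined to a capsule
  shaft running inferiorly along -Y.

Default prominence positions are conservative: everyday activity ranges clear
them, while extreme motions (deep external rotation against the ischium) or
enlarged bone morphologies produce bone-bone contact.  Real CT-derived meshes
can be loaded instead via :func:`load_mesh`.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import trimesh

from .frames import CupOrientation, cup_axis
from .mesh import MeshSurface, load_mesh  # re-exported reader

__all__ = [
    "SurrogateAnatomySpec",
    "build_pelvis_surrogate",
    "build_femur_surrogate",
    "load_mesh",
]

_BONE_SDF_RES = 0.7  # mm; bone contact needs less resolution than the rim


def _default_aiis() -> tuple:
    return ((28.0, 46.0, -4.0), 8.0)


def _default_ischium() -> tuple:
    return ((-22.0, -40.0, -6.0), 10.0)


@dataclass(frozen=True)
class SurrogateAnatomySpec:
    """Dimensions (mm / degrees) of the schematic hemipelvis and femur.

    Bump entries are ``((x, y, z) offset from the hip COR, radius)``; a radius
    of zero omits the bump.
    """

    acetabulum_diameter: float = 56.0
    acetabular_wall_thickness: float = 5.0
    acetabular_rim_margin: float = 15.0  # deg the bony margin recedes from 90
    native_opening: CupOrientation = field(
        default_factory=lambda: CupOrientation(45.0, 20.0)
    )
    aiis: tuple = field(default_factory=_default_aiis)
    ischium: tuple = field(default_factory=_default_ischium)
    femoral_neck_diameter: float = 26.0
    femoral_neck_shaft_angle: float = 135.0
    collar_span: tuple = (22.0, 40.0)  # mm along the neck axis from the COR
    shaft_diameter: float = 28.0
    shaft_length: float = 110.0
    mesh_density: float = 1.5
    side: str = "right"

    def __post_init__(self) -> None:
        errors = []
        if self.acetabulum_diameter <= 0:
            errors.append("acetabulum_diameter must be > 0")
        if self.acetabular_wall_thickness <= 0:
            errors.append("acetabular_wall_thickness must be > 0")
        if self.femoral_neck_diameter <= 0:
            errors.append("femoral_neck_diameter must be > 0 (degenerate neck)")
        if self.shaft_diameter <= 0 or self.shaft_length <= 0:
            errors.append("shaft dimensions must be > 0")
        if not 90.0 < self.femoral_neck_shaft_angle <= 180.0:
            errors.append("femoral_neck_shaft_angle must be in (90, 180]")
        if not 0 <= self.collar_span[0] < self.collar_span[1]:
            errors.append("collar_span must be an increasing non-negative pair")
        if self.side not in ("right", "left"):
            errors.append("side must be 'right' or 'left'")
        cavity_r = self.acetabulum_diameter / 2.0
        for name, (offset, radius) in (("aiis", self.aiis), ("ischium", self.ischium)):
            if radius < 0:
                errors.append(f"{name} radius must be >= 0")
            elif radius > 0:
                gap = float(np.linalg.norm(offset)) - radius - cavity_r
                if gap <= 0:
                    errors.append(
                        f"{name} bump intersects the acetabular cavity "
                        f"(shortfall {-gap:.1f} mm)"
                    )
        if errors:
            raise ValueError("invalid anatomy spec: " + "; ".join(errors))

    @property
    def neck_axis(self) -> np.ndarray:
        a = math.radians(180.0 - self.femoral_neck_shaft_angle)
        return np.array([0.0, -math.cos(a), math.sin(a)])


def _align_z(axis: np.ndarray) -> np.ndarray:
    """4x4 transform rotating +Z onto the given unit axis."""
    return trimesh.geometry.align_vectors([0.0, 0.0, 1.0], axis)


def _bump(offset, radius: float, density: float) -> trimesh.Trimesh:
    sub = max(int(math.ceil(math.log2(max(1.05 * radius / density, 1.0)))), 2)
    s = trimesh.creation.icosphere(subdivisions=min(sub, 6), radius=radius)
    s.apply_translation(offset)
    return s


def build_pelvis_surrogate(spec: SurrogateAnatomySpec) -> MeshSurface:
    """Schematic hemipelvis: acetabular wall plus AIIS and ischium bumps.

    The acetabular cavity is a hemisphere of ``acetabulum_diameter`` centred at
    the origin (the hip COR), opening along ``native_opening``.
    """
    ri = spec.acetabulum_diameter / 2.0
    ro = ri + spec.acetabular_wall_thickness
    density = spec.mesh_density

    def arc(r, t0, t1):
        n = max(int(math.ceil(math.radians(abs(t1 - t0)) * r / density)), 4)
        th = np.radians(np.linspace(t0, t1, n + 1))
        return np.column_stack([r * np.sin(th), r * np.cos(th)])

    t0 = 90.0 + spec.acetabular_rim_margin
    profile = np.vstack([arc(ri, t0, 180.0), arc(ro, 180.0, t0)])
    profile = np.vstack([profile, profile[0]])
    sections = max(int(math.ceil(2 * math.pi * ro / density)), 16)
    body = trimesh.creation.revolve(profile, sections=sections)
    body.process(validate=True)
    if body.volume < 0:
        body.invert()
    opening = CupOrientation(
        spec.native_opening.inclination, spec.native_opening.anteversion, "right"
    )
    body.apply_transform(_align_z(cup_axis(opening)))

    parts = [body]
    for offset, radius in (spec.aiis, spec.ischium):
        if radius > 0:
            parts.append(_bump(np.asarray(offset, dtype=float), radius, density))
    pelvis = trimesh.util.concatenate(parts)
    surf = MeshSurface(pelvis, "pelvis", sdf_resolution=_BONE_SDF_RES)
    if spec.side == "left":
        surf = surf.mirrored_z()
    return surf.validate(strict=True)


def build_femur_surrogate(spec: SurrogateAnatomySpec) -> MeshSurface:
    """Schematic proximal femur: osseous neck collar plus shaft capsule.

    Built in the neutral femoral frame (head resected; the prosthetic head
    centre is the origin); the shaft runs along -Y.
    """
    density = spec.mesh_density
    a0 = spec.neck_axis
    s0, s1 = spec.collar_span
    rc = spec.femoral_neck_diameter / 2.0

    profile = np.array([[0.0, s0], [rc, s0], [rc, s1], [0.0, s1], [0.0, s0]])
    sections = max(int(math.ceil(2 * math.pi * rc / density)), 16)
    collar = trimesh.creation.revolve(profile, sections=sections)
    collar.process(validate=True)
    if collar.volume < 0:
        collar.invert()
    collar.apply_transform(_align_z(a0))

    rs = spec.shaft_diameter / 2.0
    # shaft axis sits at the neck-shaft junction, giving the proximal femur
    # its lateral offset; the capsule cap overlaps the collar end for continuity
    top = a0 * (s1 + 12.0)
    # capsule spans z in [-h/2 - r, h/2 + r] about the origin; orient along -Y
    # with its apex at `top` and its distal cap at y = -shaft_length
    height = max(spec.shaft_length + top[1] - 2.0 * rs, rs)
    shaft = trimesh.creation.capsule(radius=rs, height=height)
    rot = trimesh.geometry.align_vectors([0.0, 0.0, 1.0], [0.0, -1.0, 0.0])
    shaft.apply_transform(rot)
    centre = np.array([top[0], top[1] - height / 2.0 - rs, top[2]])
    shaft.apply_translation(centre)

    femur = trimesh.util.concatenate([collar, shaft])
    surf = MeshSurface(femur, "femur", sdf_resolution=_BONE_SDF_RES)
    if spec.side == "left":
        surf = surf.mirrored_z()
    return surf.validate(strict=True)
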