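"""Parametric total-hip-replacement component geometry.

Builds watertight triangle meshes for the four prosthetic solids — femoral
head, femoral neck, acetabular liner and acetabular shell — from a handful of
dimensions, together with the closed-form descriptors of the same geometry
(neck cone half-angle, liner rim opening angle, oscillation angle) that serve
as an independent analytic oracle for the mesh-based collision pipeline.

Local frames:

* head: sphere centred at the origin (the head centre / COR);
* neck: cone (or cylinder) with apex at the origin, axis +Z, extending to
  ``neck_length``;
* liner and shell: axisymmetric about +Z with +Z the cup *opening* axis; the
  liner's bearing surface spans polar angles [rim_opening_half_angle, 180 deg]
  measured from +Z, so 90 deg is exactly hemispherical and larger values give
  a shallower (sub-hemispherical) liner.

Default dimensions describe a large-head metal-on-polyethylene construct:
36 mm head articulating in a polyethylene liner seated in a 56 mm shell, with
a generic tapered neck.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import trimesh

from .mesh import MeshSurface

__all__ = ["ImplantSpec", "build_components", "oscillation_half_angle"]


@dataclass(frozen=True)
class ImplantSpec:
    """Parametric dimensions (mm / degrees) of the implanted components."""

    head_diameter: float = 36.0
    shell_diameter: float = 56.0
    shell_thickness: float = 4.0
    radial_clearance: float = 0.1
    liner_inner_diameter: float | None = None  # default: head + 2 * clearance
    neck_shape: str = "cone"  # cone | cylinder
    neck_cone_half_angle: float = 11.0
    neck_cylinder_diameter: float = 13.0
    neck_length: float = 40.0
    neck_shaft_angle: float = 135.0
    rim_opening_half_angle: float = 90.0
    rim_chamfer_angle: float = 0.0
    mesh_density: float = 1.5  # target edge length, mm

    def __post_init__(self) -> None:
        errors = []
        if self.liner_inner_diameter is None:
            object.__setattr__(
                self,
                "liner_inner_diameter",
                self.head_diameter + 2.0 * self.radial_clearance,
            )
        for name in (
            "head_diameter",
            "shell_diameter",
            "shell_thickness",
            "liner_inner_diameter",
            "neck_cylinder_diameter",
            "neck_length",
            "mesh_density",
        ):
            if getattr(self, name) <= 0:
                errors.append(f"{name} must be > 0")
        if self.head_diameter >= self.shell_diameter:
            errors.append("head_diameter must be < shell_diameter")
        if self.liner_inner_diameter < self.head_diameter:
            errors.append("liner_inner_diameter must be >= head_diameter")
        if self.liner_inner_diameter >= self.shell_diameter - 2 * self.shell_thickness:
            errors.append(
                "liner_inner_diameter must leave room inside the shell "
                "(< shell_diameter - 2 * shell_thickness)"
            )
        if self.neck_shape not in ("cone", "cylinder"):
            errors.append("neck_shape must be 'cone' or 'cylinder'")
        if self.neck_shape == "cone" and not (
            0.0 < self.neck_cone_half_angle < self.rim_opening_half_angle
        ):
            errors.append("need 0 < neck_cone_half_angle < rim_opening_half_angle")
        if not 0.0 < self.rim_opening_half_angle <= 120.0:
            errors.append("rim_opening_half_angle must be in (0, 120]")
        if self.radial_clearance < 0:
            errors.append("radial_clearance must be >= 0")
        if not 90.0 < self.neck_shaft_angle <= 180.0:
            errors.append("neck_shaft_angle must be in (90, 180]")
        if errors:
            raise ValueError("invalid implant spec: " + "; ".join(errors))

    # -- derived analytic descriptors ---------------------------------------
    @property
    def head_radius(self) -> float:
        return self.head_diameter / 2.0

    @property
    def liner_inner_radius(self) -> float:
        return self.liner_inner_diameter / 2.0

    @property
    def liner_outer_radius(self) -> float:
        return self.shell_diameter / 2.0 - self.shell_thickness

    @property
    def clearance(self) -> float:
        return (self.liner_inner_diameter - self.head_diameter) / 2.0

    @property
    def neck_axis_neutral(self) -> np.ndarray:
        """Unit neck axis (head centre -> stem) in the neutral femoral frame.

        Lies in the coronal plane, tilted laterally from the -Y shaft
        direction by (180 - neck_shaft_angle)."""
        a = math.radians(180.0 - self.neck_shaft_angle)
        return np.array([0.0, -math.cos(a), math.sin(a)])

    def with_density(self, mesh_density: float) -> "ImplantSpec":
        return replace(self, mesh_density=mesh_density)


def oscillation_half_angle(spec: ImplantSpec) -> float:
    """Angle (degrees) between neck axis and cup opening axis at which the
    neck cone first touches the liner rim circle.

    Closed form for a conical neck articulating in a spherical liner whose rim
    circle sits at ``rim_opening_half_angle`` from the opening axis: contact
    occurs when the angular gap between the neck axis and the rim circle
    shrinks to the cone half-angle, i.e. at
    ``rim_opening_half_angle - neck_cone_half_angle``.
    """
    if spec.neck_shape != "cone":
        raise ValueError(
            "oscillation_half_angle is defined for conical necks only; "
            "use the mesh-based first-contact search for cylinder necks"
        )
    return spec.rim_opening_half_angle - spec.neck_cone_half_angle


# ---------------------------------------------------------------------------
# mesh construction
# ---------------------------------------------------------------------------


def _sections(radius: float, density: float) -> int:
    return max(int(math.ceil(2.0 * math.pi * radius / density)), 16)


def _arc(r: float, theta0: float, theta1: float, density: float) -> np.ndarray:
    """Polyline (radial, z) along a circle of radius r, polar angle from +Z."""
    n = max(int(math.ceil(math.radians(abs(theta1 - theta0)) * r / density)), 4)
    th = np.radians(np.linspace(theta0, theta1, n + 1))
    return np.column_stack([r * np.sin(th), r * np.cos(th)])


def _revolve_solid(profile: np.ndarray, density: float, r_max: float) -> trimesh.Trimesh:
    """Revolve a closed (r, z) profile about +Z into a watertight solid."""
    # drop consecutive duplicates; ensure closure
    keep = [0]
    for i in range(1, len(profile)):
        if np.linalg.norm(profile[i] - profile[keep[-1]]) > 1e-9:
            keep.append(i)
    prof = profile[keep]
    if np.linalg.norm(prof[0] - prof[-1]) > 1e-9:
        prof = np.vstack([prof, prof[0]])
    mesh = trimesh.creation.revolve(prof, sections=_sections(r_max, density))
    mesh.process(validate=True)
    if mesh.volume < 0:
        mesh.invert()
    return mesh


def _icosphere(radius: float, density: float) -> trimesh.Trimesh:
    # icosahedron edge ~1.05 r; each subdivision halves the edge
    sub = max(int(math.ceil(math.log2(max(1.05 * radius / density, 1.0)))), 2)
    return trimesh.creation.icosphere(subdivisions=min(sub, 7), radius=radius)


def _build_head(spec: ImplantSpec) -> trimesh.Trimesh:
    return _icosphere(spec.head_radius, spec.mesh_density)


def _build_neck(spec: ImplantSpec) -> trimesh.Trimesh:
    length = spec.neck_length
    if spec.neck_shape == "cone":
        r_end = length * math.tan(math.radians(spec.neck_cone_half_angle))
        # slender cones need fine axial steps near the apex for the SDF band
        n_ax = max(int(math.ceil(length / spec.mesh_density)), 4)
        zs = np.linspace(0.0, length, n_ax + 1)
        side = np.column_stack([zs * (r_end / length), zs])
        profile = np.vstack([[0.0, 0.0], side, [0.0, length]])
        return _revolve_solid(profile, spec.mesh_density, r_end)
    r = spec.neck_cylinder_diameter / 2.0
    profile = np.array([[0.0, 0.0], [r, 0.0], [r, length], [0.0, length]])
    return _revolve_solid(profile, spec.mesh_density, r)


def _build_liner(spec: ImplantSpec) -> trimesh.Trimesh:
    ri, ro = spec.liner_inner_radius, spec.liner_outer_radius
    rim = spec.rim_opening_half_angle
    cham = spec.rim_chamfer_angle
    density = spec.mesh_density
    inner = _arc(ri, rim + cham, 180.0, density)
    outer = _arc(ro, 180.0, rim, density)
    profile = [inner, outer]
    if cham > 0.0:
        # conical bevel widening the opening from the bearing edge to the rim
        profile = [inner, outer, _arc_chamfer(ri, ro, rim, cham)]
    profile = np.vstack(profile)
    return _revolve_solid(profile, density, ro)


def _arc_chamfer(ri: float, ro: float, rim: float, cham: float) -> np.ndarray:
    # straight bevel from the outer rim circle to the recessed bearing edge
    p_outer = np.array([ro * math.sin(math.radians(rim)), ro * math.cos(math.radians(rim))])
    p_inner = np.array(
        [ri * math.sin(math.radians(rim + cham)), ri * math.cos(math.radians(rim + cham))]
    )
    return np.vstack([p_outer, p_inner])


def _build_shell(spec: ImplantSpec) -> trimesh.Trimesh:
    ro = spec.shell_diameter / 2.0
    ri = ro - spec.shell_thickness
    profile = np.vstack(
        [_arc(ri, 90.0, 180.0, spec.mesh_density), _arc(ro, 180.0, 90.0, spec.mesh_density)]
    )
    return _revolve_solid(profile, spec.mesh_density, ro)


def build_components(spec: ImplantSpec) -> dict[str, MeshSurface]:
    """Build the four component solids as validated watertight meshes.

    Returns a dict with keys ``head``, ``neck``, ``liner``, ``shell``, each a
    :class:`MeshSurface` in its local frame (see module docstring).
    """
    sdf_res = max(spec.mesh_density / 3.0, 0.15)
    out = {}
    for label, builder in (
        ("head", _build_head),
        ("neck", _build_neck),
        ("liner", _build_liner),
        ("shell", _build_shell),
    ):
        surf = MeshSurface(builder(spec), label, sdf_resolution=sdf_res)
        surf.validate(strict=True)
        out[label] = surf
    return out
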