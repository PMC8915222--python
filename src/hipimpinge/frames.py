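"""Coordinate conventions, joint-angle rotation composition, and cup-axis geometry.

Pelvic frame (right hip): +X anterior, +Y superior, +Z lateral, origin at the hip
centre of rotation (COR).  In neutral stance the femoral frame coincides with the
pelvic frame and the femoral shaft points along -Y.  The anterior pelvic plane is
the X-Y plane.

Joint angles follow a fixed Cardan sequence, applied intrinsically:

1. flexion (+) / extension (-) about the medio-lateral axis (Z),
2. adduction (+) / abduction (-) about the rotated anterior axis (X'),
3. internal (+) / external (-) rotation about the femoral shaft axis (Y'').

Cup orientation uses the radiographic convention (Murray): anteversion is the
angle between the cup opening axis and the coronal (Y-Z) plane, positive tilting
anteriorly; inclination is the angle between inferior (-Y) and the coronal-plane
projection of the opening axis, the opening swinging laterally.

Degrees are the external unit everywhere; radians appear only internally.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "RigidTransform",
    "JointAngles",
    "CupOrientation",
    "GimbalLockError",
    "rotation_from_joint_angles",
    "joint_angles_from_rotation",
    "cup_axis",
    "cup_orientation_from_axis",
    "mirror_z",
]

_EULER_SEQ = "ZXY"  # intrinsic flexion -> adduction -> internal rotation
_ORTHO_TOL = 1e-9


class GimbalLockError(ValueError):
    """Raised when joint angles cannot be recovered because |adduction| = 90 deg."""


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid-body transform: x_world = rotation @ x_local + translation.

    rotation is a 3x3 proper orthonormal matrix (dimensionless), translation a
    3-vector in mm.
    """

    rotation: np.ndarray
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        rot = np.asarray(self.rotation, dtype=float)
        tra = np.asarray(self.translation, dtype=float)
        if rot.shape != (3, 3):
            raise ValueError(f"rotation must be 3x3, got {rot.shape}")
        if tra.shape != (3,):
            raise ValueError(f"translation must be a 3-vector, got {tra.shape}")
        if not np.all(np.isfinite(rot)) or not np.all(np.isfinite(tra)):
            raise ValueError("non-finite rigid transform")
        err = np.abs(rot.T @ rot - np.eye(3)).max()
        if err > 1e-6:
            raise ValueError(f"rotation not orthonormal (max error {err:.2e})")
        if np.linalg.det(rot) < 0:
            raise ValueError("rotation must be proper (det +1), got a reflection")
        object.__setattr__(self, "rotation", rot)
        object.__setattr__(self, "translation", tra)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_rotation(cls, rotation: np.ndarray) -> "RigidTransform":
        return cls(np.asarray(rotation, dtype=float), np.zeros(3))

    @classmethod
    def from_translation(cls, translation) -> "RigidTransform":
        return cls(np.eye(3), np.asarray(translation, dtype=float))

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: (self @ other)(x) = self(other(x))."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    __matmul__ = compose

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to one point or an (n, 3) array of points."""
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def apply_vector(self, vectors: np.ndarray) -> np.ndarray:
        """Rotate direction vectors (no translation)."""
        return np.asarray(vectors, dtype=float) @ self.rotation.T

    def is_orthonormal(self, tol: float = _ORTHO_TOL) -> bool:
        rot = self.rotation
        return (
            float(np.abs(rot.T @ rot - np.eye(3)).max()) <= tol
            and abs(float(np.linalg.det(rot)) - 1.0) <= tol
        )


@dataclass(frozen=True)
class JointAngles:
    """Hip joint angles in degrees: flexion(+)/extension(-),
    adduction(+)/abduction(-), internal(+)/external(-) rotation."""

    flexion: float
    adduction: float
    rotation: float

    def __post_init__(self) -> None:
        for name, v in self.as_dict().items():
            if not math.isfinite(v):
                raise ValueError(f"{name} angle is not finite: {v!r}")
            if not -180.0 < v <= 180.0:
                raise ValueError(f"{name} angle {v} outside (-180, 180]")

    def as_array(self) -> np.ndarray:
        return np.array([self.flexion, self.adduction, self.rotation], dtype=float)

    def as_dict(self) -> dict:
        return {
            "flexion": float(self.flexion),
            "adduction": float(self.adduction),
            "rotation": float(self.rotation),
        }

    @classmethod
    def neutral(cls) -> "JointAngles":
        return cls(0.0, 0.0, 0.0)


@dataclass(frozen=True)
class CupOrientation:
    """Radiographic cup orientation in degrees."""

    inclination: float
    anteversion: float
    side: str = "right"

    def __post_init__(self) -> None:
        if not 0.0 <= self.inclination <= 90.0:
            raise ValueError(f"inclination {self.inclination} outside [0, 90]")
        if not -90.0 <= self.anteversion <= 90.0:
            raise ValueError(f"anteversion {self.anteversion} outside [-90, 90]")
        if self.side not in ("right", "left"):
            raise ValueError(f"side must be 'right' or 'left', got {self.side!r}")


def rotation_from_joint_angles(angles: JointAngles) -> RigidTransform:
    """Rotation transform of the femur (relative to pelvis) at the given angles.

    Pure rotation about the COR; translation is zero.
    """
    arr = angles.as_array()
    rot = Rotation.from_euler(_EULER_SEQ, arr, degrees=True)
    return RigidTransform.from_rotation(rot.as_matrix())


def joint_angles_from_rotation(
    t: RigidTransform, gimbal_tol: float = 1e-7
) -> JointAngles:
    """Recover joint angles from a rotation transform (angle read-back).

    Raises GimbalLockError when |adduction| is within ``gimbal_tol`` degrees of
    90, where flexion and internal rotation are not separable.
    """
    if not t.is_orthonormal(tol=1e-6):
        raise ValueError("transform rotation is not orthonormal")
    m = t.rotation
    # For the intrinsic Z-X-Y sequence, sin(adduction) = m[2, 1].
    s_add = float(np.clip(m[2, 1], -1.0, 1.0))
    if 90.0 - math.degrees(math.asin(abs(s_add))) < gimbal_tol:
        raise GimbalLockError(
            "adduction within tolerance of +/-90 deg: flexion and rotation "
            "are degenerate in this configuration"
        )
    add = math.degrees(math.asin(s_add))
    flex = math.degrees(math.atan2(-m[0, 1], m[1, 1]))
    rot = math.degrees(math.atan2(-m[2, 0], m[2, 2]))
    return JointAngles(flex, add, rot)


def cup_axis(orientation: CupOrientation) -> np.ndarray:
    """Unit opening axis of the cup in the pelvic frame.

    At (0, 0) the opening points inferiorly (0, -1, 0); inclination swings it
    laterally in the coronal plane; anteversion tilts it anteriorly out of the
    coronal plane.  Left-side axes mirror +Z.
    """
    inc = math.radians(orientation.inclination)
    av = math.radians(orientation.anteversion)
    n = np.array(
        [
            math.sin(av),
            -math.cos(av) * math.cos(inc),
            math.cos(av) * math.sin(inc),
        ]
    )
    if orientation.side == "left":
        n = mirror_z(n)
    return n


def cup_orientation_from_axis(n: np.ndarray, side: str = "right") -> CupOrientation:
    """Invert :func:`cup_axis`: recover radiographic angles from an opening axis."""
    v = np.asarray(n, dtype=float)
    norm = np.linalg.norm(v)
    if not np.isfinite(norm) or norm == 0:
        raise ValueError("axis must be a finite non-zero vector")
    v = v / norm
    if side == "left":
        v = mirror_z(v)
    av = math.degrees(math.asin(float(np.clip(v[0], -1.0, 1.0))))
    inc = math.degrees(math.atan2(v[2], -v[1]))
    return CupOrientation(inclination=inc, anteversion=av, side=side)


def mirror_z(v: np.ndarray) -> np.ndarray:
    """Mirror a vector through the sagittal-ish X-Y plane (lateral sign flip)."""
    out = np.array(v, dtype=float)
    out[..., 2] = -out[..., 2]
    return out
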