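"""Joint-angle trajectories for dislocation-prone activities of daily living.

The synthetic generator emulates the seven classic dislocation-prone ADLs plus
level walking as coupled three-axis motions: each axis (flexion/extension,
adduction/abduction, internal/external rotation) rises smoothly from neutral
to its peak as a raised cosine, with a per-axis phase offset so all three axes
move simultaneously — the point of simulating recorded activity kinematics
rather than single-axis sweeps.  Peak values are configurable approximations
of gait-lab ranges for these activities, not recorded subject data; users with
measured trajectories load them from CSV instead.

Default templates:

==========  =====================================  ======================
label       activity                               character
==========  =====================================  ======================
SSL         sit-to-stand, low seat                 deep flexion + int. rot.
SSN         sit-to-stand, normal chair             flexion + int. rot.
XLG         leg crossing while seated              flexion + adduction + int. rot.
TIE         shoe tying while seated                deep flexion + adduction
STOOP       bending to the floor while standing    deep flexion
PIVOT       rotating the upper body away standing  extension + ext. rot.
ROLL        rolling over supine                    extension + ext. rot.
WALK        level walking                          gait-scale motion
==========  =====================================  ======================

SSL/SSN/XLG/TIE/STOOP are flexion-dominant (posterior-dislocation-prone);
PIVOT/ROLL are extension/external-rotation-dominant (anterior-prone).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .frames import JointAngles, rotation_from_joint_angles, joint_angles_from_rotation
from .frames import RigidTransform

__all__ = [
    "ActivityTemplate",
    "Trajectory",
    "DEFAULT_TEMPLATES",
    "POSTERIOR_PRONE",
    "ANTERIOR_PRONE",
    "synthesize",
    "read_trajectory_csv",
    "write_trajectory_csv",
    "reference_points",
    "angles_from_reference_points",
]

_CSV_COLUMNS = ("time", "flexion", "adduction", "rotation")

POSTERIOR_PRONE = ("SSL", "SSN", "XLG", "TIE", "STOOP")
ANTERIOR_PRONE = ("PIVOT", "ROLL")


@dataclass(frozen=True)
class ActivityTemplate:
    """Parameterised activity: per-axis peaks (deg), phase offsets, duration."""

    label: str
    peak_flexion: float
    peak_adduction: float
    peak_rotation: float
    phase_offsets: tuple = (0.0, 0.10, 0.15)  # fraction of cycle per axis
    duration: float = 2.0  # s
    n_samples: int = 49

    def __post_init__(self) -> None:
        if self.n_samples < 16:
            raise ValueError("n_samples must be >= 16")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if not all(0.0 <= p < 1.0 for p in self.phase_offsets):
            raise ValueError("phase offsets must be in [0, 1)")
        for p in (self.peak_flexion, self.peak_adduction, self.peak_rotation):
            if not np.isfinite(p) or not -180.0 < p <= 180.0:
                raise ValueError(f"peak {p} outside (-180, 180]")

    @property
    def peaks(self) -> np.ndarray:
        return np.array(
            [self.peak_flexion, self.peak_adduction, self.peak_rotation], dtype=float
        )


DEFAULT_TEMPLATES: dict[str, ActivityTemplate] = {
    t.label: t
    for t in (
        ActivityTemplate("SSL", 100.0, 8.0, 12.0),
        ActivityTemplate("SSN", 92.0, 10.0, 18.0),
        ActivityTemplate("XLG", 82.0, 22.0, 22.0),
        ActivityTemplate("TIE", 105.0, 14.0, 14.0),
        ActivityTemplate("STOOP", 106.0, 8.0, 10.0),
        ActivityTemplate("PIVOT", -10.0, -8.0, -60.0),
        ActivityTemplate("ROLL", -20.0, -12.0, -55.0),
        ActivityTemplate("WALK", 30.0, 7.0, 8.0, duration=1.1),
    )
}


@dataclass(frozen=True)
class Trajectory:
    """Time series of hip joint angles for one activity."""

    name: str
    times: np.ndarray  # (n,) s, strictly increasing
    angles: np.ndarray  # (n, 3) deg: flexion, adduction, rotation

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        a = np.asarray(self.angles, dtype=float)
        if t.ndim != 1 or len(t) < 2:
            raise ValueError("trajectory needs >= 2 samples")
        if a.shape != (len(t), 3):
            raise ValueError(f"angles shape {a.shape} != ({len(t)}, 3)")
        if not np.all(np.diff(t) > 0):
            raise ValueError("time must be strictly increasing")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(a))):
            raise ValueError("non-finite trajectory data")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "angles", a)

    def __len__(self) -> int:
        return len(self.times)

    @property
    def fractions(self) -> np.ndarray:
        """Normalised time in [0, 1] per sample."""
        t = self.times
        return (t - t[0]) / (t[-1] - t[0])

    def joint_angles(self, i: int) -> JointAngles:
        return JointAngles(*self.angles[i])

    def interpolate(self, fraction: float) -> JointAngles:
        """Joint angles at a trajectory fraction, each axis linear in time."""
        f = float(np.clip(fraction, 0.0, 1.0))
        vals = [np.interp(f, self.fractions, self.angles[:, k]) for k in range(3)]
        return JointAngles(*vals)

    @property
    def peak_angles(self) -> np.ndarray:
        return self.angles[np.abs(self.angles).argmax(axis=0), [0, 1, 2]]


def synthesize(template: ActivityTemplate) -> Trajectory:
    """Deterministic raised-cosine trajectory from neutral to the peaks.

    Axis k stays at zero until its phase offset, then follows half a cosine
    cycle to its peak, reaching it at the end of the activity.
    """
    u = np.linspace(0.0, 1.0, template.n_samples)
    cols = []
    for peak, phase in zip(template.peaks, template.phase_offsets):
        s = np.clip((u - phase) / (1.0 - phase), 0.0, 1.0)
        cols.append(peak * 0.5 * (1.0 - np.cos(np.pi * s)))
    return Trajectory(
        name=template.label,
        times=u * template.duration,
        angles=np.column_stack(cols),
    )


def read_trajectory_csv(path: str | Path, name: str | None = None) -> Trajectory:
    """Read ``time,flexion,adduction,rotation`` CSV (seconds / degrees).

    Lines starting with ``#`` are comments; the sign convention (flexion +,
    adduction +, internal rotation +) is asserted in the header comment
    written by :func:`write_trajectory_csv`.
    """
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    return Trajectory(
        name=name or path.stem,
        times=df["time"].to_numpy(dtype=float),
        angles=df[list(_CSV_COLUMNS[1:])].to_numpy(dtype=float),
    )


def write_trajectory_csv(trajectory: Trajectory, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(
            "# hip joint trajectory: seconds, degrees; "
            "flexion+/extension-, adduction+/abduction-, internal+/external- rotation\n"
        )
        pd.DataFrame(
            {
                "time": trajectory.times,
                "flexion": trajectory.angles[:, 0],
                "adduction": trajectory.angles[:, 1],
                "rotation": trajectory.angles[:, 2],
            }
        ).to_csv(fh, index=False, float_format="%.12g")


def reference_points(
    angles: JointAngles, distal_offset: float = 100.0, lateral_offset: float = 50.0
) -> tuple[np.ndarray, np.ndarray]:
    """Images of the two femur-fixed reference points under the joint rotation.

    The femur pose is encoded by a distal point (0, -distal_offset, 0) on the
    shaft and a lateral point (0, 0, +lateral_offset); their world positions
    fully determine the rotation.
    """
    if distal_offset <= 0 or lateral_offset <= 0:
        raise ValueError("offsets must be > 0")
    t = rotation_from_joint_angles(angles)
    distal = t.apply([0.0, -distal_offset, 0.0])
    lateral = t.apply([0.0, 0.0, lateral_offset])
    return distal, lateral


def angles_from_reference_points(
    distal: np.ndarray, lateral: np.ndarray,
    distal_offset: float = 100.0, lateral_offset: float = 50.0,
) -> JointAngles:
    """Invert :func:`reference_points` (away from gimbal lock)."""
    ey = -np.asarray(distal, dtype=float) / distal_offset
    ez = np.asarray(lateral, dtype=float) / lateral_offset
    ex = np.cross(ey, ez)
    rot = np.column_stack([ex, ey, ez])
    return joint_angles_from_rotation(RigidTransform.from_rotation(rot))
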