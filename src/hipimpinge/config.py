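"""Declarative run configuration for the command-line interface.

A single YAML file describes a complete run: implant dimensions, anatomy
(surrogate spec or mesh paths), placement, activities, sweep grid, collision
tolerances and the output directory.  Every key has a default; the effective
(fully resolved) configuration is echoed into the output manifest so runs are
reproducible from their outputs alone.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .anatomy import SurrogateAnatomySpec, build_femur_surrogate, build_pelvis_surrogate
from .frames import CupOrientation
from .implant import ImplantSpec
from .kinematics import (
    DEFAULT_TEMPLATES,
    ActivityTemplate,
    Trajectory,
    read_trajectory_csv,
    synthesize,
)
from .mesh import load_mesh
from .placement import StemAngles, build_scene
from .sweep import SweepGrid

__all__ = ["RunConfig", "load_config"]


@dataclass(frozen=True)
class CollisionConfig:
    volume_threshold_mm3: float = 1.0
    bisection_tolerance_deg: float = 0.1

    def __post_init__(self) -> None:
        if self.volume_threshold_mm3 <= 0 or self.bisection_tolerance_deg <= 0:
            raise ValueError("collision tolerances must be > 0")


@dataclass(frozen=True)
class AnatomyConfig:
    surrogate: SurrogateAnatomySpec = field(default_factory=SurrogateAnatomySpec)
    pelvis_mesh: str | None = None
    femur_mesh: str | None = None
    mesh_scale: float = 1.0  # 1000 for metre-based files
    include_bones: bool = True


@dataclass(frozen=True)
class PlacementConfig:
    stem: StemAngles = field(default_factory=StemAngles)
    medialise_mm: float = 0.0
    head_mode: str = "concentric"  # concentric | contact


@dataclass(frozen=True)
class RunConfig:
    """Fully resolved configuration of one simulation or sweep run."""

    implant: ImplantSpec = field(default_factory=ImplantSpec)
    anatomy: AnatomyConfig = field(default_factory=AnatomyConfig)
    placement: PlacementConfig = field(default_factory=PlacementConfig)
    activities: tuple = tuple(DEFAULT_TEMPLATES)  # labels, templates or CSV paths
    grid: SweepGrid = field(default_factory=SweepGrid)
    collision: CollisionConfig = field(default_factory=CollisionConfig)
    output_dir: str = "hipimpinge_out"

    def trajectories(self) -> list[Trajectory]:
        out = []
        for entry in self.activities:
            if isinstance(entry, Trajectory):
                out.append(entry)
            elif isinstance(entry, ActivityTemplate):
                out.append(synthesize(entry))
            elif isinstance(entry, str) and entry in DEFAULT_TEMPLATES:
                out.append(synthesize(DEFAULT_TEMPLATES[entry]))
            elif isinstance(entry, str):
                path = Path(entry)
                if not path.exists():
                    raise FileNotFoundError(
                        f"activity {entry!r} is neither a known template label "
                        f"({', '.join(DEFAULT_TEMPLATES)}) nor an existing CSV"
                    )
                out.append(read_trajectory_csv(path))
            else:
                raise TypeError(f"unsupported activity entry {entry!r}")
        if not out:
            raise ValueError("no activities configured")
        return out

    def build_scene(self, cup: CupOrientation):
        anatomy = self.anatomy
        pelvis = femur = None
        if anatomy.pelvis_mesh:
            pelvis = load_mesh(anatomy.pelvis_mesh, "pelvis", scale=anatomy.mesh_scale)
        elif anatomy.include_bones:
            pelvis = build_pelvis_surrogate(anatomy.surrogate)
        if anatomy.femur_mesh:
            femur = load_mesh(anatomy.femur_mesh, "femur", scale=anatomy.mesh_scale)
        elif anatomy.include_bones:
            femur = build_femur_surrogate(anatomy.surrogate)
        return build_scene(
            implant_spec=self.implant,
            anatomy_spec=anatomy.surrogate,
            cup=cup,
            stem=self.placement.stem,
            medialise=self.placement.medialise_mm,
            head_mode=self.placement.head_mode,
            include_bones=anatomy.include_bones,
            pelvis=pelvis,
            femur=femur,
        )

    def to_dict(self) -> dict:
        """Effective configuration as plain data (for the run manifest)."""

        def encode(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {
                    f.name: encode(getattr(obj, f.name))
                    for f in dataclasses.fields(obj)
                }
            if isinstance(obj, (tuple, list)):
                return [encode(v) for v in obj]
            return obj

        return encode(self)


def _build(cls, data: dict, **overrides):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown {cls.__name__} key(s): {sorted(unknown)}")
    return cls(**{**data, **overrides})


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Load a YAML run configuration; missing keys fall back to defaults.

    Keyword overrides replace whole top-level sections.
    """
    raw: dict = {}
    if path is not None:
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"config file not found: {path}")
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: top level must be a mapping")

    sections: dict = {}
    if "implant" in raw:
        sections["implant"] = _build(ImplantSpec, raw["implant"])
    if "anatomy" in raw:
        data = dict(raw["anatomy"])
        if "surrogate" in data:
            surro = dict(data["surrogate"])
            for key in ("aiis", "ischium"):
                if key in surro:
                    off_r = surro[key]
                    surro[key] = (tuple(off_r[0]), float(off_r[1]))
            data["surrogate"] = _build(SurrogateAnatomySpec, surro)
        sections["anatomy"] = _build(AnatomyConfig, data)
    if "placement" in raw:
        data = dict(raw["placement"])
        if "stem" in data:
            data["stem"] = _build(StemAngles, data["stem"])
        sections["placement"] = _build(PlacementConfig, data)
    if "activities" in raw:
        entries = []
        for entry in raw["activities"]:
            if isinstance(entry, dict):
                entries.append(_build(ActivityTemplate, entry))
            else:
                entries.append(entry)
        sections["activities"] = tuple(entries)
    if "sweep" in raw:
        data = raw["sweep"]
        sections["grid"] = SweepGrid(
            tuple(data.get("inclinations", SweepGrid().inclinations)),
            tuple(data.get("anteversions", SweepGrid().anteversions)),
        )
    if "collision" in raw:
        sections["collision"] = _build(CollisionConfig, raw["collision"])
    if "output_dir" in raw:
        sections["output_dir"] = str(raw["output_dir"])

    sections.update(overrides)
    return RunConfig(**sections)
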