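"""Cup-orientation sweeps: impingement matrices, frequency map, safe zone.

Runs the activity battery over a grid of radiographic cup orientations.  Each
grid cell re-places only the acetabular components (stem and bones fixed), so
mesh geometry and distance fields are shared across the whole sweep.  Outputs:

* one impingement matrix per activity: cell -> none / component / bone /
  component-and-bone, with the underlying event retained;
* a frequency map counting, per cell, the activities producing component
  impingement (component-and-bone counts as component);
* impingement-free zones: cells whose component-impingement count does not
  exceed a chosen limit, with the intersection against the classic Lewinnek
  window (30-50 deg inclination, 5-25 deg anteversion) reported alongside.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable

import numpy as np
import pandas as pd

from .collision import (
    DEFAULT_BISECTION_TOL,
    DEFAULT_VOLUME_THRESHOLD,
    ImpingementEvent,
    first_impingement,
)
from .frames import CupOrientation
from .kinematics import Trajectory
from .placement import ImplantedScene

__all__ = [
    "SweepGrid",
    "ImpingementMatrix",
    "SafeZone",
    "LEWINNEK_INCLINATION",
    "LEWINNEK_ANTEVERSION",
    "run_sweep",
    "frequency_map",
    "safe_zone",
    "write_sweep_outputs",
]

LEWINNEK_INCLINATION = (30.0, 50.0)
LEWINNEK_ANTEVERSION = (5.0, 25.0)

_OUTCOME_CODES = {
    "none": "N",
    "component": "C",
    "bone": "B",
    "component_and_bone": "CB",
}


@dataclass(frozen=True)
class SweepGrid:
    """Sorted grids of inclination and anteversion angles (degrees)."""

    inclinations: tuple = tuple(range(30, 75, 5))
    anteversions: tuple = tuple(range(0, 55, 5))

    def __post_init__(self) -> None:
        for name in ("inclinations", "anteversions"):
            vals = tuple(float(v) for v in getattr(self, name))
            if len(vals) == 0:
                raise ValueError(f"{name} must be non-empty")
            if len(set(vals)) != len(vals) or list(vals) != sorted(vals):
                raise ValueError(f"{name} must be sorted and unique")
            object.__setattr__(self, name, vals)

    @property
    def cells(self) -> list[tuple[float, float]]:
        return [(i, a) for i in self.inclinations for a in self.anteversions]

    def __len__(self) -> int:
        return len(self.inclinations) * len(self.anteversions)


@dataclass
class ImpingementMatrix:
    """Per-activity outcome over the cup-orientation grid."""

    activity: str
    grid: SweepGrid
    outcomes: dict = field(default_factory=dict)  # (inc, av) -> outcome str
    events: dict = field(default_factory=dict)  # (inc, av) -> ImpingementEvent|None

    def __post_init__(self) -> None:
        missing = set(self.grid.cells) - set(self.outcomes)
        extra = set(self.outcomes) - set(self.grid.cells)
        if missing or extra:
            raise ValueError(
                f"{self.activity}: outcomes must cover the grid exactly "
                f"({len(missing)} missing, {len(extra)} extra)"
            )

    def component_cells(self) -> set:
        """Cells with component impingement (component-and-bone included)."""
        return {c for c, o in self.outcomes.items() if "component" in o}

    def to_dataframe(self) -> pd.DataFrame:
        """Rows = inclination, columns = anteversion, values = N/C/B/CB."""
        df = pd.DataFrame(
            index=pd.Index(self.grid.inclinations, name="inclination_deg"),
            columns=pd.Index(self.grid.anteversions, name="anteversion_deg"),
            dtype=object,
        )
        for (inc, av), outcome in self.outcomes.items():
            df.loc[inc, av] = _OUTCOME_CODES[outcome]
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path)


def run_sweep(
    scene_builder: Callable[[CupOrientation], ImplantedScene],
    grid: SweepGrid,
    trajectories: Iterable[Trajectory],
    threshold: float = DEFAULT_VOLUME_THRESHOLD,
    tolerance_deg: float = DEFAULT_BISECTION_TOL,
    progress: Callable[[str], None] | None = None,
) -> list[ImpingementMatrix]:
    """Evaluate every (cell, activity) pair; deterministic and order-free.

    ``scene_builder`` maps a :class:`CupOrientation` to an implanted scene —
    typically ``scene.with_cup`` of a prototype scene so meshes are shared.
    """
    trajectories = list(trajectories)
    matrices = []
    for traj in trajectories:
        outcomes, events = {}, {}
        for inc, av in grid.cells:
            scene = scene_builder(CupOrientation(inc, av))
            ev = first_impingement(
                scene, traj, tolerance_deg=tolerance_deg, threshold=threshold
            )
            outcomes[(inc, av)] = ev.kind if ev is not None else "none"
            events[(inc, av)] = ev
            if progress is not None:
                progress(
                    f"{traj.name} inc={inc:g} av={av:g}: "
                    f"{outcomes[(inc, av)]}"
                )
        matrices.append(
            ImpingementMatrix(
                activity=traj.name, grid=grid, outcomes=outcomes, events=events
            )
        )
    return matrices


def frequency_map(matrices: list[ImpingementMatrix]) -> pd.DataFrame:
    """Per-cell count of activities with component impingement.

    Rows = inclination, columns = anteversion, integer counts in
    [0, n_activities]; component-and-bone events count as component.
    """
    if not matrices:
        raise ValueError("at least one matrix required")
    grid = matrices[0].grid
    for m in matrices[1:]:
        if m.grid != grid:
            raise ValueError("matrices must share one grid")
    counts = pd.DataFrame(
        0,
        index=pd.Index(grid.inclinations, name="inclination_deg"),
        columns=pd.Index(grid.anteversions, name="anteversion_deg"),
        dtype=int,
    )
    for m in matrices:
        for inc, av in m.component_cells():
            counts.loc[inc, av] += 1
    return counts


@dataclass(frozen=True)
class SafeZone:
    """Cells meeting the impingement-count criterion, plus Lewinnek overlap."""

    max_impinging_activities: int
    cells: frozenset
    lewinnek_cells: frozenset

    def to_dict(self) -> dict:
        return {
            "max_impinging_activities": self.max_impinging_activities,
            "cells": sorted(self.cells),
            "lewinnek_cells": sorted(self.lewinnek_cells),
        }


def lewinnek_box(grid: SweepGrid) -> set:
    return {
        (i, a)
        for i, a in grid.cells
        if LEWINNEK_INCLINATION[0] <= i <= LEWINNEK_INCLINATION[1]
        and LEWINNEK_ANTEVERSION[0] <= a <= LEWINNEK_ANTEVERSION[1]
    }


def safe_zone(
    freq: pd.DataFrame, max_impinging_activities: int, n_activities: int | None = None
) -> SafeZone:
    """Cells whose component-impingement count <= ``max_impinging_activities``.

    Also reports the intersection with the Lewinnek window.
    """
    if max_impinging_activities < 0:
        raise ValueError("max_impinging_activities must be >= 0")
    if n_activities is not None and max_impinging_activities > n_activities:
        raise ValueError("max_impinging_activities exceeds the activity count")
    grid = SweepGrid(tuple(freq.index), tuple(freq.columns))
    cells = {
        (i, a) for i, a in grid.cells if freq.loc[i, a] <= max_impinging_activities
    }
    return SafeZone(
        max_impinging_activities=max_impinging_activities,
        cells=frozenset(cells),
        lewinnek_cells=frozenset(cells & lewinnek_box(grid)),
    )


def write_sweep_outputs(
    directory,
    matrices: list[ImpingementMatrix],
    max_impinging_activities: int = 0,
) -> dict:
    """Write matrix CSVs, the frequency CSV and the safe-zone JSON summary."""
    import json

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files = {}
    for m in matrices:
        path = directory / f"matrix_{m.activity}.csv"
        m.to_csv(path)
        files[m.activity] = path.name
    freq = frequency_map(matrices)
    freq.to_csv(directory / "frequency.csv")
    zone = safe_zone(freq, max_impinging_activities, n_activities=len(matrices))
    summary = {
        "activities": [m.activity for m in matrices],
        "matrix_files": files,
        "frequency_file": "frequency.csv",
        "safe_zone": zone.to_dict(),
        "events": {
            m.activity: {
                f"{inc:g}/{av:g}": ev.to_dict()
                for (inc, av), ev in m.events.items()
                if ev is not None
            }
            for m in matrices
        },
    }
    with open(directory / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary
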