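"""Shared fixtures.

Heavy geometry (component meshes, bone surrogates and their signed-distance
fields) is built once per session and shared; scenes derived from it only
re-pose meshes, so caches stay warm.  The full activity-battery sweep is a
session fixture because several acceptance properties read different aspects
of the same run.
"""
from __future__ import annotations

import numpy as np
import pytest

from hipimpinge import (
    CupOrientation,
    ImplantSpec,
    SweepGrid,
    build_components,
    build_scene,
    run_sweep,
    synthesize,
)
from hipimpinge.anatomy import (
    SurrogateAnatomySpec,
    build_femur_surrogate,
    build_pelvis_surrogate,
)
from hipimpinge.kinematics import DEFAULT_TEMPLATES
from hipimpinge.placement import StemAngles


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture(scope="session")
def default_components():
    return build_components(ImplantSpec())


@pytest.fixture(scope="session")
def default_bones():
    spec = SurrogateAnatomySpec()
    return build_pelvis_surrogate(spec), build_femur_surrogate(spec)


@pytest.fixture(scope="session")
def default_scene(default_components, default_bones):
    pelvis, femur = default_bones
    return build_scene(
        components=default_components,
        cup=CupOrientation(45.0, 20.0),
        pelvis=pelvis,
        femur=femur,
    )


@pytest.fixture(scope="session")
def boneless_scene(default_components):
    return build_scene(
        components=default_components,
        cup=CupOrientation(45.0, 20.0),
        include_bones=False,
    )


@pytest.fixture(scope="session")
def straight_neck_scene():
    """Axisymmetric oracle scene: straight 10 deg cone neck pointing along the
    shaft (-Y), hemispherical liner opening inferiorly, no bones.  Pure
    flexion sweeps the neck axis directly from the cup pole toward the rim, so
    first contact occurs at the analytic oscillation half-angle (80 deg)."""
    spec = ImplantSpec(neck_shaft_angle=180.0, neck_cone_half_angle=10.0)
    return build_scene(
        implant_spec=spec,
        cup=CupOrientation(0.0, 0.0),
        stem=StemAngles(0.0, 0.0, 0.0),
        include_bones=False,
    )


@pytest.fixture(scope="session")
def battery(default_scene):
    """Full default battery: 8 activities x 99-cell grid, one shared run."""
    trajectories = [synthesize(t) for t in DEFAULT_TEMPLATES.values()]
    return run_sweep(default_scene.with_cup, SweepGrid(), trajectories)


@pytest.fixture(scope="session")
def battery_by_label(battery):
    return {m.activity: m for m in battery}
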