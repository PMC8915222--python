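"""Sweep mechanics: grids, matrices, frequency map, safe zone."""
import numpy as np
import pandas as pd
import pytest

from hipimpinge import (
    CupOrientation,
    SweepGrid,
    frequency_map,
    run_sweep,
    safe_zone,
    synthesize,
)
from hipimpinge.kinematics import ActivityTemplate, DEFAULT_TEMPLATES
from hipimpinge.sweep import ImpingementMatrix, lewinnek_box


def make_matrix(grid, activity, component_cells=(), bone_cells=()):
    outcomes = {}
    for cell in grid.cells:
        if cell in component_cells:
            outcomes[cell] = "component"
        elif cell in bone_cells:
            outcomes[cell] = "bone"
        else:
            outcomes[cell] = "none"
    return ImpingementMatrix(activity=activity, grid=grid, outcomes=outcomes)


class TestSweepGrid:
    def test_default_grid_is_99_cells(self):
        grid = SweepGrid()
        assert len(grid) == 99
        assert len(grid.inclinations) == 9
        assert len(grid.anteversions) == 11

    def test_unsorted_rejected(self):
        with pytest.raises(ValueError):
            SweepGrid(inclinations=(40, 30), anteversions=(0, 5))
        with pytest.raises(ValueError):
            SweepGrid(inclinations=(30, 30), anteversions=(0, 5))
        with pytest.raises(ValueError):
            SweepGrid(inclinations=(), anteversions=(0,))

    def test_matrix_requires_full_coverage(self):
        grid = SweepGrid(inclinations=(30, 40), anteversions=(0, 10))
        with pytest.raises(ValueError, match="cover the grid"):
            ImpingementMatrix("X", grid, outcomes={(30.0, 0.0): "none"})


@pytest.fixture(scope="module")
def small_grid():
    return SweepGrid(inclinations=(40.0, 60.0), anteversions=(10.0, 30.0))


class TestRunSweep:

    def test_walking_sweep_clear_and_deterministic(self, default_scene, small_grid):
        walk = synthesize(DEFAULT_TEMPLATES["WALK"])
        m1 = run_sweep(default_scene.with_cup, small_grid, [walk])[0]
        m2 = run_sweep(default_scene.with_cup, small_grid, [walk])[0]
        assert set(m1.outcomes.values()) == {"none"}
        assert m1.outcomes == m2.outcomes

    def test_cells_independent_of_evaluation_order(self, default_scene, small_grid):
        """Evaluating a cell in isolation matches the value from the sweep."""
        ramp = synthesize(
            ActivityTemplate("ER", 0.0, 0.0, -90.0, phase_offsets=(0, 0, 0))
        )
        matrix = run_sweep(default_scene.with_cup, small_grid, [ramp])[0]
        from hipimpinge.collision import first_impingement

        for cell in [(60.0, 30.0), (40.0, 10.0)]:
            ev = first_impingement(default_scene.with_cup(CupOrientation(*cell)), ramp)
            expected = ev.kind if ev else "none"
            assert matrix.outcomes[cell] == expected

    def test_matrix_csv_round_trip(self, default_scene, small_grid, tmp_path):
        walk = synthesize(DEFAULT_TEMPLATES["WALK"])
        matrix = run_sweep(default_scene.with_cup, small_grid, [walk])[0]
        path = tmp_path / "m.csv"
        matrix.to_csv(path)
        df = pd.read_csv(path, index_col=0)
        assert df.shape == (2, 2)
        assert set(df.to_numpy().ravel()) == {"N"}


class TestFrequencyMap:
    grid = SweepGrid(inclinations=(30.0, 40.0), anteversions=(0.0, 10.0, 20.0))

    def test_empty_battery_rejected(self):
        with pytest.raises(ValueError):
            frequency_map([])

    def test_all_zero_without_events(self):
        freq = frequency_map([make_matrix(self.grid, "A")])
        assert int(freq.to_numpy().sum()) == 0

    def test_single_activity_everywhere_gives_ones(self):
        m = make_matrix(self.grid, "A", component_cells=set(self.grid.cells))
        freq = frequency_map([m])
        assert np.all(freq.to_numpy() == 1)

    def test_counts_conserve_activity_totals(self):
        """Sum over the map equals the summed per-activity component-cell
        counts; bone-only events never contribute."""
        m1 = make_matrix(
            self.grid, "A",
            component_cells={(30.0, 0.0), (30.0, 10.0)},
            bone_cells={(40.0, 20.0)},
        )
        m2 = make_matrix(self.grid, "B", component_cells={(30.0, 0.0)})
        freq = frequency_map([m1, m2])
        assert int(freq.to_numpy().sum()) == len(m1.component_cells()) + len(
            m2.component_cells()
        )
        assert freq.loc[30.0, 0.0] == 2
        assert freq.loc[40.0, 20.0] == 0

    def test_mismatched_grids_rejected(self):
        other = SweepGrid(inclinations=(30.0,), anteversions=(0.0,))
        with pytest.raises(ValueError, match="share"):
            frequency_map([make_matrix(self.grid, "A"), make_matrix(other, "B")])


class TestSafeZone:
    grid = SweepGrid(inclinations=(30.0, 40.0), anteversions=(0.0, 10.0, 20.0))

    def test_max_equal_to_activity_count_is_whole_grid(self):
        m = make_matrix(self.grid, "A", component_cells=set(self.grid.cells))
        zone = safe_zone(frequency_map([m]), 1, n_activities=1)
        assert zone.cells == frozenset(self.grid.cells)

    def test_zero_tolerance_on_saturated_map_is_empty(self):
        m = make_matrix(self.grid, "A", component_cells=set(self.grid.cells))
        zone = safe_zone(frequency_map([m]), 0, n_activities=1)
        assert zone.cells == frozenset()

    def test_lewinnek_box_on_default_grid_is_25_cells(self):
        assert len(lewinnek_box(SweepGrid())) == 25

    def test_limit_validated(self):
        m = make_matrix(self.grid, "A")
        with pytest.raises(ValueError):
            safe_zone(frequency_map([m]), 3, n_activities=1)
        with pytest.raises(ValueError):
            safe_zone(frequency_map([m]), -1)
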