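"""Cellular-automaton engine: neighborhood, inertia, allocation, assessment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import cohen_kappa_score

from lucsim import ca, reference
from lucsim.ca import CAParams, TransitionRules
from lucsim.raster import CategoricalRaster


def all_allowed(k=7):
    return TransitionRules(pd.DataFrame(np.ones((k, k), dtype=int)))


class TestNeighborhoodEffect:
    def test_uniform_map_interior_density_one(self):
        land = CategoricalRaster(np.full((9, 9), 3, dtype=np.int64))
        eff = ca.neighborhood_effect(land, 3)
        np.testing.assert_allclose(eff[1:-1, 1:-1], 1.0)

    def test_absent_class_density_zero(self):
        land = CategoricalRaster(np.full((9, 9), 3, dtype=np.int64))
        np.testing.assert_allclose(ca.neighborhood_effect(land, 5), 0.0)

    def test_single_cell_moore_window(self):
        grid = np.ones((7, 7), dtype=np.int64)
        grid[3, 3] = 7
        eff = ca.neighborhood_effect(CategoricalRaster(grid), 7)
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr or dc:
                    assert eff[3 + dr, 3 + dc] == pytest.approx(1 / 8)
        assert eff[3, 3] == 0.0
        assert eff[0, 0] == 0.0

    def test_edges_use_truncated_window(self):
        grid = np.ones((5, 5), dtype=np.int64)
        grid[0, 1] = 7
        eff = ca.neighborhood_effect(CategoricalRaster(grid), 7)
        # the corner sees 3 neighbors, one of which is class 7
        assert eff[0, 0] == pytest.approx(1 / 3)


class TestAdaptiveInertia:
    def test_unchanged_when_gap_not_worse(self):
        assert ca.adaptive_inertia(2.0, d_prev=50, d_prev2=60) == 2.0
        assert ca.adaptive_inertia(2.0, d_prev=-50, d_prev2=-50) == 2.0

    def test_worsening_overshoot_releases_cells(self):
        # two-step toy: overshoot doubled, inertia halves (x -100/-200)
        assert ca.adaptive_inertia(1.0, d_prev=-200, d_prev2=-100) == pytest.approx(0.5)

    def test_worsening_underallocation_strengthens(self):
        assert ca.adaptive_inertia(1.0, d_prev=200, d_prev2=100) == pytest.approx(2.0)
        assert ca.adaptive_inertia(1.0, d_prev=300, d_prev2=100) > \
            ca.adaptive_inertia(1.0, d_prev=150, d_prev2=100)

    def test_zero_previous_gap_keeps_inertia(self):
        assert ca.adaptive_inertia(1.5, d_prev=10, d_prev2=0) == 1.5

    def test_floor_clamp(self):
        out = ca.adaptive_inertia(1e-3, d_prev=-1000, d_prev2=-1, inertia_floor=1e-3)
        assert out == 1e-3


class TestCombinedProbability:
    def uniform_inputs(self, grid, rules):
        k = len(rules.codes)
        suit = {c: np.full(grid.shape, 1.0) for c in rules.codes}
        neigh = {c: np.full(grid.shape, 1.0) for c in rules.codes}
        inertia = {c: 1.0 for c in rules.codes}
        return suit, neigh, inertia

    def test_symmetric_inputs_give_uniform_distribution(self):
        grid = np.ones((4, 4), dtype=np.int64)
        rules = all_allowed()
        suit, neigh, inertia = self.uniform_inputs(grid, rules)
        dist = ca.combined_probability(suit, neigh, inertia, rules,
                                       CategoricalRaster(grid))
        np.testing.assert_allclose(dist, 1 / 7)

    def test_frozen_cell_point_mass(self):
        grid = np.full((3, 3), 5, dtype=np.int64)
        rules = all_allowed()
        suit, neigh, inertia = self.uniform_inputs(grid, rules)
        mask = np.zeros((3, 3), dtype=bool)
        mask[1, 1] = True
        dist = ca.combined_probability(suit, neigh, inertia, rules,
                                       CategoricalRaster(grid), mask=mask)
        np.testing.assert_allclose(dist[4, 1, 1], 1.0)  # class 5 at position 4
        assert dist[:, 1, 1].sum() == pytest.approx(1.0)

    def test_ecological_rules_zero_forbidden_targets_for_forest(self, rules):
        grid = np.full((2, 2), 3, dtype=np.int64)  # forest everywhere
        suit, neigh, inertia = self.uniform_inputs(grid, rules)
        dist = ca.combined_probability(suit, neigh, inertia, rules,
                                       CategoricalRaster(grid))
        # forest row permits only forest, water, wet land
        for j, code in enumerate(rules.codes):
            if code in (3, 5, 6):
                assert (dist[j] > 0).all()
            else:
                np.testing.assert_allclose(dist[j], 0.0)

    def test_all_zero_scores_keep_current_class(self):
        grid = np.full((2, 2), 2, dtype=np.int64)
        rules = all_allowed()
        suit = {c: np.zeros((2, 2)) for c in rules.codes}
        neigh = {c: np.zeros((2, 2)) for c in rules.codes}
        inertia = {c: 1.0 for c in rules.codes}
        dist = ca.combined_probability(suit, neigh, inertia, rules,
                                       CategoricalRaster(grid))
        np.testing.assert_allclose(dist[1], 1.0)


class TestRouletteSelect:
    def test_point_mass_always_selected(self, rng):
        for _ in range(10):
            assert ca.roulette_select([0.0, 1.0, 0.0], rng) == 1

    def test_long_run_frequency(self):
        rng = np.random.default_rng(0)
        draws = [ca.roulette_select([0.5, 0.5], rng) for _ in range(100_000)]
        assert np.mean(draws) == pytest.approx(0.5, abs=0.01)

    def test_seeded_sequence_identical(self):
        a = [ca.roulette_select([0.3, 0.7], np.random.default_rng(9)) for _ in range(5)]
        b = [ca.roulette_select([0.3, 0.7], np.random.default_rng(9)) for _ in range(5)]
        assert a == b

    def test_unnormalized_rejected(self, rng):
        with pytest.raises(ValueError, match="sum to 1"):
            ca.roulette_select([0.5, 0.2], rng)


def flat_suit(grid_shape, codes):
    return {c: np.full(grid_shape, 1.0 / len(codes)) for c in codes}


class TestRunAllocation:
    def test_demand_equal_to_composition_changes_nothing_needed(self, rng):
        grid = rng.integers(1, 8, size=(20, 20)).astype(np.int64)
        land = CategoricalRaster(grid)
        rules = all_allowed()
        demand = {c: int((grid == c).sum()) for c in rules.codes}
        final, log = ca.run_allocation(land, flat_suit(grid.shape, rules.codes),
                                       rules, None, demand, CAParams(seed=1))
        np.testing.assert_array_equal(final.grid, grid)
        assert log.empty

    def test_moves_demand_between_classes_within_tolerance(self, rng):
        grid = np.ones((20, 20), dtype=np.int64)
        grid[:10] = 7
        land = CategoricalRaster(grid)
        rules = all_allowed()
        demand = {c: 0 for c in rules.codes}
        demand[1] = 170
        demand[7] = 230  # move 30 paddy cells to built-up
        params = CAParams(seed=2, demand_tolerance=2, max_iterations=50)
        final, log = ca.run_allocation(land, flat_suit(grid.shape, rules.codes),
                                       rules, None, demand, params)
        counts = final.class_counts()
        assert abs(counts[7] - 230) <= 2 and abs(counts[1] - 170) <= 2
        assert final.grid.size == grid.size

    def test_frozen_cells_never_change(self, toy_landscape, rules):
        land = toy_landscape.copy()
        land.grid = land.grid.copy()
        land.grid[land.grid == 8] = 7
        mask = land.grid == 5
        demand = {c: int((land.grid == c).sum()) for c in rules.codes}
        demand[1] -= 40
        demand[7] += 40
        final, _ = ca.run_allocation(land, flat_suit(land.shape, rules.codes),
                                     rules, mask, demand, CAParams(seed=3))
        np.testing.assert_array_equal(final.grid[mask], land.grid[mask])

    def test_no_forbidden_transition_persists(self, toy_landscape, rules):
        land = toy_landscape.copy()
        land.grid = land.grid.copy()
        land.grid[land.grid == 8] = 7
        demand = {c: int((land.grid == c).sum()) for c in rules.codes}
        demand[1] -= 30
        demand[2] -= 20
        demand[5] += 30
        demand[7] += 20
        final, _ = ca.run_allocation(land, flat_suit(land.shape, rules.codes),
                                     rules, None, demand, CAParams(seed=4))
        for i in rules.codes:
            for j in rules.codes:
                if i != j and not rules.allows(i, j):
                    assert int(((land.grid == i) & (final.grid == j)).sum()) == 0

    def test_wrong_demand_total_rejected(self, toy_landscape, rules):
        land = toy_landscape.copy()
        land.grid = land.grid.copy()
        land.grid[land.grid == 8] = 7
        demand = {c: int((land.grid == c).sum()) for c in rules.codes}
        demand[1] += 5
        with pytest.raises(ValueError, match="sum"):
            ca.run_allocation(land, flat_suit(land.shape, rules.codes),
                              rules, None, demand, CAParams(seed=0))

    def test_infeasible_demand_fails_before_iterating(self, rules):
        # all water: nothing may convert, yet built-up demand is nonzero
        grid = np.full((5, 5), 5, dtype=np.int64)
        land = CategoricalRaster(grid)
        demand = {c: 0 for c in rules.codes}
        demand[5] = 20
        demand[7] = 5
        with pytest.raises(ValueError, match="[Ii]nfeasible"):
            ca.run_allocation(land, flat_suit(grid.shape, rules.codes),
                              rules, None, demand, CAParams(seed=0))


class TestSampleCells:
    def test_full_fraction_returns_every_cell(self, toy_landscape, rng):
        idx = ca.sample_cells(toy_landscape, 1.0, rng)
        assert sorted(idx.tolist()) == list(range(toy_landscape.grid.size))

    def test_one_percent_of_reference_grid(self, rng):
        raster = CategoricalRaster(np.ones((186, 188), dtype=np.int64))  # 34,968 cells
        idx = ca.sample_cells(raster, 0.01, rng)
        assert idx.size == 350

    def test_seeded_sample_identical(self, toy_landscape):
        a = ca.sample_cells(toy_landscape, 0.05, np.random.default_rng(4))
        b = ca.sample_cells(toy_landscape, 0.05, np.random.default_rng(4))
        np.testing.assert_array_equal(a, b)


class TestAssessAccuracy:
    def test_identical_labels_perfect_scores(self, rng):
        labels = rng.integers(1, 8, size=500)
        cm = ca.assess_accuracy(labels, labels)
        assert cm.overall_accuracy == 1.0 and cm.kappa == 1.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ca.assess_accuracy([], [])

    def test_study_confusion_counts_reproduce_printed_metrics(self):
        cm = ca.confusion_from_counts(reference.validation_confusion_counts())
        assert round(cm.overall_accuracy * 100, 2) == 91.75
        assert round(cm.kappa, 4) == 0.8935
        assert cm.n == 34968

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(st.integers(2, 10), st.integers(0, 2 ** 16))
    def test_kappa_matches_sklearn_oracle(self, k, seed):
        rng = np.random.default_rng(seed)
        actual = rng.integers(0, k, size=300)
        simulated = np.where(rng.random(300) < 0.6, actual, rng.integers(0, k, size=300))
        cm = ca.assess_accuracy(actual, simulated)
        assert cm.kappa == pytest.approx(
            cohen_kappa_score(actual, simulated), abs=1e-12)

    def test_marginal_bruteforce_kappa(self, rng):
        """Closed-form kappa equals the brute-force marginal computation."""
        actual = rng.integers(1, 6, size=400)
        simulated = rng.integers(1, 6, size=400)
        cm = ca.assess_accuracy(actual, simulated)
        n = len(actual)
        po = np.mean(actual == simulated)
        pe = sum(np.mean(actual == c) * np.mean(simulated == c) for c in range(1, 6))
        assert cm.overall_accuracy == pytest.approx(po, abs=1e-12)
        assert cm.kappa == pytest.approx((po - pe) / (1 - pe), abs=1e-12)


class TestRulesLoading:
    def test_packaged_scenario_matrix(self, rules):
        expected = np.array([
            [1, 1, 1, 1, 1, 1, 1],
            [1, 1, 1, 1, 1, 1, 1],
            [0, 0, 1, 0, 1, 1, 0],
            [0, 0, 1, 1, 1, 1, 0],
            [0, 0, 0, 0, 1, 0, 0],
            [0, 0, 0, 0, 1, 1, 0],
            [1, 1, 1, 1, 1, 1, 1]])
        np.testing.assert_array_equal(rules.matrix, expected)

    def test_zero_diagonal_rejected(self):
        m = np.ones((3, 3), dtype=int)
        m[1, 1] = 0
        with pytest.raises(ValueError, match="diagonal"):
            TransitionRules(pd.DataFrame(m))

    def test_non_binary_rejected(self):
        m = np.ones((3, 3))
        m[0, 1] = 0.5
        with pytest.raises(ValueError, match="0 or 1"):
            TransitionRules(pd.DataFrame(m))
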