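"""Performance measures, order statistic, LI profiles, clonal ribbons."""

import numpy as np
import pytest

from cryptabm.engine import RunConfig, RunResult
from cryptabm.geometry import find_contacts
from cryptabm.measures import (MeasureTargets, cell_order, column_index,
                               label_s_phase, li_profile, mark_clones,
                               mature_cell_order, performance_summary,
                               ribbon_gap_statistic, summarize_replicates)
from cryptabm.state import PHASE_A, PHASE_G0, PHASE_S

from conftest import make_state, random_state


def brute_force_order(state, geometry):
    """Direct per-cell recomputation of the order statistic."""
    i, j = find_contacts(state.x, state.y, state.r, geometry, 0.0)
    n = state.n
    neighbours = [[] for _ in range(n)]
    for a, b in zip(i, j):
        neighbours[a].append(b)
        neighbours[b].append(a)
    mature = state.mature
    orders = np.ones(n)
    for c in range(n):
        if neighbours[c]:
            orders[c] = np.mean([mature[k] for k in neighbours[c]])
    return orders


class TestCellOrder:
    def test_fraction_of_mature_neighbours(self):
        is_mature = np.array([True, True, True, True, False, False, False])
        # cell 0 touches 1..6: three mature of six neighbours
        pairs = (np.zeros(6, dtype=int), np.arange(1, 7))
        assert cell_order(is_mature, pairs)[0] == pytest.approx(0.5)

    def test_all_mature_neighbours_give_one(self):
        is_mature = np.ones(7, dtype=bool)
        pairs = (np.zeros(6, dtype=int), np.arange(1, 7))
        assert cell_order(is_mature, pairs)[0] == 1.0

    def test_isolated_cell_has_order_one(self):
        empty = (np.empty(0, dtype=int), np.empty(0, dtype=int))
        assert cell_order(np.array([True]), empty)[0] == 1.0

    def test_matches_brute_force_on_random_snapshot(self, geometry, rng):
        s = random_state(rng, geometry, n=120)
        pairs = find_contacts(s.x, s.y, s.r, geometry, 0.0)
        assert np.allclose(cell_order(s.mature, pairs),
                           brute_force_order(s, geometry))

    def test_mature_order_mixed_crypt_below_one(self, geometry):
        # a mature cell touching one proliferative cell drags the mean down
        s = make_state([10.0, 18.0, 40.0], [10.0, 10.0, 10.0],
                       phase=[PHASE_G0, PHASE_A, PHASE_G0])
        assert 0.0 <= mature_cell_order(s, geometry) < 1.0

    def test_no_mature_cells_is_nan(self, geometry):
        s = make_state([10.0], [10.0], phase=PHASE_A)
        assert np.isnan(mature_cell_order(s, geometry))

    def test_invariant_under_lateral_rotation(self, geometry, rng):
        s = random_state(rng, geometry, n=80)
        before = mature_cell_order(s, geometry)
        s.x = np.mod(s.x + 37.123, geometry.width)
        assert mature_cell_order(s, geometry) == pytest.approx(before)


def synthetic_result(n_total, n_mature, exits, geometry,
                     onset=10.0, snapshots=()):
    n_total = np.asarray(n_total, dtype=float)
    n_mature = np.asarray(n_mature, dtype=float)
    t = np.arange(1, n_total.size + 1, dtype=float)
    cfg = RunConfig(geometry=geometry)
    return RunResult(
        t_h=t, n_total=n_total, n_proliferative=n_total - n_mature,
        n_mature=n_mature, n_stem=np.zeros_like(n_total),
        exits_per_h=np.asarray(exits, dtype=float), steady_onset_h=onset,
        snapshots=list(snapshots),
        final_state=make_state([1.0], [1.0]), config=cfg,
        reached_steady=True)


class TestPerformanceSummary:
    def test_normalised_cell_number_at_target(self, geometry):
        res = synthetic_result(np.full(34, 704.0), np.full(34, 504.0),
                               np.zeros(34), geometry)
        pm = performance_summary(res)
        assert pm.normalised["n_cells"] == pytest.approx(1.0)

    def test_mature_proportion_from_reference_composition(self, geometry):
        res = synthetic_result(np.full(34, 704.0), np.full(34, 504.0),
                               np.zeros(34), geometry)
        pm = performance_summary(res)
        assert pm.mature_proportion == pytest.approx(504 / 704)
        assert pm.normalised["mature_proportion"] == pytest.approx(1.0)

    def test_production_rate_counts_exits(self, geometry):
        exits = np.zeros(34)
        exits[10:] = 1.0   # 24 removals over the 24 h past onset
        res = synthetic_result(np.full(34, 704.0), np.full(34, 504.0),
                               exits, geometry)
        pm = performance_summary(res)
        assert pm.production_rate == pytest.approx(1.0)

    def test_run_without_steady_state_is_flagged(self, geometry):
        res = synthetic_result(np.arange(34.0), np.zeros(34),
                               np.zeros(34), geometry)
        res.reached_steady = False
        pm = performance_summary(res)
        assert not pm.reached_steady and np.isnan(pm.n_cells)

    def test_replicate_aggregation_excludes_failures(self, geometry):
        good = performance_summary(synthetic_result(
            np.full(34, 700.0), np.full(34, 500.0), np.zeros(34), geometry))
        bad_res = synthetic_result(np.arange(34.0), np.zeros(34),
                                   np.zeros(34), geometry)
        bad_res.reached_steady = False
        bad = performance_summary(bad_res)
        agg = summarize_replicates([good, bad])
        assert agg["replicates"] == 2 and agg["completed"] == 1
        assert agg["n_cells_mean"] == pytest.approx(700.0)


class TestLIProfile:
    def test_no_s_phase_cells_all_zero(self, geometry):
        s = make_state([10.0, 20.0], [5.0, 5.0], phase=PHASE_A)
        label_s_phase(s)
        prof = li_profile(s, geometry)
        assert prof[0] == 0.0

    def test_all_s_phase_cells_all_ones(self, geometry):
        s = make_state([10.0, 20.0], [5.0, 5.0], phase=PHASE_S)
        label_s_phase(s)
        assert li_profile(s, geometry)[0] == 1.0

    def test_empty_rows_are_missing_not_zero(self, geometry):
        s = make_state([10.0], [5.0], phase=PHASE_S)
        label_s_phase(s)
        prof = li_profile(s, geometry)
        assert np.isnan(prof[5])

    def test_matches_manual_binning(self, geometry):
        """Scripted toy crypt vs hand-computed row proportions."""
        rh = geometry.row_height()
        y = np.array([0.5 * rh, 0.6 * rh,          # row 0: 1 of 2 labelled
                      2.5 * rh, 2.6 * rh, 2.7 * rh])  # row 2: 2 of 3
        s = make_state(np.arange(5) * 10.0, y,
                       phase=[PHASE_S, PHASE_A, PHASE_S, PHASE_S, PHASE_A])
        label_s_phase(s)
        prof = li_profile(s, geometry)
        assert prof[0] == pytest.approx(0.5)
        assert prof[2] == pytest.approx(2 / 3)
        assert np.isnan(prof[1])

    def test_relabelling_invariance(self, geometry, rng):
        s = random_state(rng, geometry, n=60)
        s.li_label[:] = rng.random(60) < 0.4
        perm = rng.permutation(60)
        assert np.allclose(li_profile(s, geometry),
                           li_profile(s.take(perm), geometry),
                           equal_nan=True)


class TestClones:
    def test_mark_clones_picks_distinct_base_cells(self, geometry, rng):
        s = make_state(np.arange(22) * 10.0, np.full(22, 5.0))
        mark_clones(s, 4, rng, geometry)
        marked = s.clone[s.clone >= 0]
        assert len(marked) == 4 and len(np.unique(marked)) == 4

    def test_too_many_clones_rejected(self, geometry, rng):
        s = make_state([10.0, 20.0], [5.0, 5.0])
        with pytest.raises(ValueError):
            mark_clones(s, 3, rng, geometry)

    def test_unmoving_single_clone_has_no_gaps(self, geometry):
        s = make_state([10.0, 10.0, 10.0], [5.0, 14.0, 23.0])
        s.clone[:] = 0
        assert ribbon_gap_statistic(s, geometry) == {0: 0}

    def test_interposed_stranger_counts_one_gap(self, geometry):
        # labelled - unlabelled - labelled within one column
        s = make_state([10.0, 10.0, 10.0], [5.0, 14.0, 23.0])
        s.clone[[0, 2]] = 1
        assert ribbon_gap_statistic(s, geometry) == {1: 1}

    def test_column_index_is_lateral_binning(self, geometry, rng):
        x = rng.uniform(0, geometry.width, 500)
        w = geometry.width / geometry.n_circumference
        assert np.array_equal(column_index(x, geometry),
                              np.floor(x / w).astype(int))
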