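"""Unit tests for the suitability-model post-processing chain."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from oracles import point_segment_distance
from phyloprior.grid import ClimateStack, LandscapeGrid, PresenceMatrix
from phyloprior.sdm import (
    BinaryRange,
    apply_dispersal,
    clip_to_buffered_mcp,
    compute_tss,
    ensemble_median,
    filter_models,
    fit_suitability,
    maxtss_threshold,
    min_occurrence_filter,
    model_species,
    sample_pseudo_absences,
    split_train_test,
)


class TestSplits:
    def test_eighty_twenty_counts(self):
        splits = split_train_test(np.arange(20), np.arange(100, 130),
                                  train_frac=0.8, n_repeats=3, seed=0)
        for s in splits:
            assert s.train_presence.size == 16 and s.test_presence.size == 4
            assert s.train_absence.size == 24 and s.test_absence.size == 6

    def test_partition_property(self):
        pres, abs_ = np.arange(13), np.arange(50, 71)
        for s in split_train_test(pres, abs_, n_repeats=5, seed=1):
            assert np.array_equal(np.sort(np.r_[s.train_presence, s.test_presence]), pres)
            assert np.array_equal(np.sort(np.r_[s.train_absence, s.test_absence]), abs_)
            assert not set(s.train_presence) & set(s.test_presence)

    def test_seed_reproducible(self):
        a = split_train_test(np.arange(10), np.arange(20, 40), seed=5)
        b = split_train_test(np.arange(10), np.arange(20, 40), seed=5)
        for x, y in zip(a, b):
            assert np.array_equal(x.train_presence, y.train_presence)
            assert np.array_equal(x.train_absence, y.train_absence)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            split_train_test(np.arange(10), np.arange(10), train_frac=1.0)
        with pytest.raises(ValueError):
            split_train_test(np.arange(3), np.arange(10))


class TestSuitability:
    def test_monotone_gradient_recovered(self, grid10):
        """Presences at the warm end of a single gradient give suitability
        that increases along that gradient."""
        grad = np.linspace(-2, 2, 100)
        clim = ClimateStack(grad[:, None], ("bio10",))
        presences = np.argsort(grad)[-15:]
        absences = np.argsort(grad)[:15]
        suit = fit_suitability(presences, absences, clim, seed=0)
        rho = stats.spearmanr(suit, grad).statistic
        assert rho > 0.95

    def test_zero_variance_predictors_constant_map(self):
        clim = ClimateStack(np.zeros((50, 2)), ("a", "b"))
        suit = fit_suitability(np.arange(5), np.arange(10, 15), clim)
        assert np.allclose(suit, 0.5)

    def test_deterministic(self):
        rng = np.random.default_rng(0)
        clim = ClimateStack(rng.standard_normal((60, 3)), ("a", "b", "c"))
        a = fit_suitability(np.arange(10), np.arange(30, 40), clim, seed=1)
        b = fit_suitability(np.arange(10), np.arange(30, 40), clim, seed=1)
        assert np.array_equal(a, b)


class TestTSS:
    def test_worked_confusion_example(self):
        # TP=9 FN=1 TN=8 FP=2 -> sens 0.9, spec 0.8, TSS 0.7
        observed = np.r_[np.ones(10), np.zeros(10)].astype(bool)
        predicted = observed.copy()
        predicted[9] = False           # one missed presence
        predicted[[10, 11]] = True     # two false alarms
        ev = compute_tss(predicted, observed)
        assert ev.sensitivity == pytest.approx(0.9)
        assert ev.specificity == pytest.approx(0.8)
        assert ev.tss == pytest.approx(0.7)

    def test_perfect_and_all_present(self):
        observed = np.r_[np.ones(5), np.zeros(5)].astype(bool)
        assert compute_tss(observed, observed).tss == pytest.approx(1.0)
        ev = compute_tss(np.ones(10, bool), observed)
        assert ev.tss == pytest.approx(0.0)  # sens 1, spec 0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            compute_tss(np.ones(5, bool), np.ones(5, bool))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_bounded_and_relabel_invariant(self, seed):
        rng = np.random.default_rng(seed)
        observed = np.zeros(30, dtype=bool)
        observed[rng.choice(30, 10, replace=False)] = True
        predicted = rng.random(30) < 0.5
        ev = compute_tss(predicted, observed)
        assert -1 <= ev.tss <= 1
        perm = rng.permutation(30)
        assert compute_tss(predicted[perm], observed[perm]).tss == pytest.approx(ev.tss)


class TestMaxTSS:
    def test_separable_case_smallest_maximizer(self):
        scores = np.array([0.9, 0.8, 0.3, 0.1])
        observed = np.array([True, True, False, False])
        t, ev = maxtss_threshold(scores, observed)
        assert ev.tss == pytest.approx(1.0)
        assert t == pytest.approx(0.8)  # smallest candidate attaining max

    def test_matches_dense_grid_search(self):
        rng = np.random.default_rng(3)
        scores = rng.random(10)
        observed = rng.random(10) < 0.5
        observed[0], observed[1] = True, False  # both classes present
        t, ev = maxtss_threshold(scores, observed)
        grid_best = max(
            compute_tss(scores >= g, observed).tss
            for g in np.linspace(0, 1, 101)
        )
        assert ev.tss >= grid_best - 1e-12

    def test_inverted_scores_non_positive_gain(self):
        scores = np.array([0.1, 0.2, 0.8, 0.9])
        observed = np.array([True, True, False, False])
        _, ev = maxtss_threshold(scores, observed)
        assert ev.tss <= 0 + 1e-12

    def test_binarization_recovers_separable_truth(self):
        rng = np.random.default_rng(1)
        observed = rng.random(40) < 0.4
        observed[0], observed[1] = True, False
        scores = np.where(observed, 0.7 + 0.3 * rng.random(40),
                          0.3 * rng.random(40))
        t, _ = maxtss_threshold(scores, observed)
        assert np.array_equal(scores >= t, observed)


class TestFilterEnsemble:
    def test_threshold_inclusive(self):
        from phyloprior.sdm import ModelEvaluation
        evs = [ModelEvaluation(0.5, 0.99), ModelEvaluation(0.7, 0.8),
               ModelEvaluation(0.9, 0.8)]  # tss 0.49, 0.5, 0.7
        kept = filter_models(evs)
        assert [round(e.tss, 2) for e in kept] == [0.5, 0.7]
        assert filter_models([ModelEvaluation(0.5, 0.5)]) == []

    def test_median_rules(self):
        assert ensemble_median([np.array([0.2]), np.array([0.4]),
                                np.array([0.9])])[0] == pytest.approx(0.4)
        assert ensemble_median([np.array([0.2]), np.array([0.4])])[0] == pytest.approx(0.3)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_median_idempotent_and_permutation_invariant(self, seed):
        rng = np.random.default_rng(seed)
        maps = [rng.random(15) for _ in range(5)]
        med = ensemble_median(maps)
        assert np.array_equal(ensemble_median([med]), med)
        order = rng.permutation(5)
        assert np.allclose(ensemble_median([maps[i] for i in order]), med)


class TestMCPClip:
    def test_distant_cell_removed(self, grid10):
        # single occurrence at cell 0; a cell ~500 km away must be clipped
        occ = np.array([0])
        far = int(np.argmax((grid10.x - grid10.x[0])**2 + (grid10.y - grid10.y[0])**2))
        rng = BinaryRange("sp", frozenset({0, far}))
        d = np.hypot(grid10.x[far] - grid10.x[0], grid10.y[far] - grid10.y[0])
        assert d > 200
        clipped = clip_to_buffered_mcp(rng, occ, grid10, buffer_km=200)
        assert clipped.cells == frozenset({0})

    def test_inside_hull_identity(self, grid10):
        occ = np.array([0, 9, 90, 99])  # the four corners
        cells = frozenset(range(100))
        clipped = clip_to_buffered_mcp(BinaryRange("sp", cells), occ, grid10, 200)
        assert clipped.cells == cells

    def test_collinear_occurrences_buffered_segment(self, grid10):
        occ = np.array([0, 1, 2, 3])  # one row: a segment
        cells = frozenset(range(100))
        clipped = clip_to_buffered_mcp(BinaryRange("sp", cells), occ, grid10,
                                       buffer_km=50)
        a, b = grid10.coords[0], grid10.coords[3]
        for c in range(100):
            d = point_segment_distance(grid10.coords[c], a, b)
            if d < 50 - 1e-9:
                assert c in clipped.cells
            elif d > 50 + 1e-9:
                assert c not in clipped.cells

    def test_empty_occurrences_rejected(self, grid10):
        with pytest.raises(ValueError):
            clip_to_buffered_mcp(BinaryRange("sp", frozenset()), np.array([]), grid10)


class TestDispersal:
    def test_no_dispersal_is_intersection(self, grid10):
        cur = BinaryRange("sp", frozenset({1, 2}))
        fut = BinaryRange("sp", frozenset({2, 3}), scenario="future-x")
        out = apply_dispersal(cur, fut, "none", grid10)
        assert out.cells == frozenset({2})

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_nesting_none_limited_full(self, seed):
        grid = LandscapeGrid.regular(8, 8)
        rng = np.random.default_rng(seed)
        cur = BinaryRange("sp", frozenset(np.flatnonzero(rng.random(64) < 0.3).tolist()))
        fut = BinaryRange("sp", frozenset(np.flatnonzero(rng.random(64) < 0.3).tolist()),
                          scenario="future-x")
        none = apply_dispersal(cur, fut, "none", grid, 40.0).cells
        limited = apply_dispersal(cur, fut, "limited", grid, 40.0).cells
        full = apply_dispersal(cur, fut, "full", grid, 40.0).cells
        assert none <= limited <= full

    def test_limited_with_empty_current(self, grid10):
        cur = BinaryRange("sp", frozenset())
        fut = BinaryRange("sp", frozenset({5, 6}), scenario="future-x")
        assert apply_dispersal(cur, fut, "limited", grid10).cells == frozenset()

    def test_unknown_scenario_rejected(self, grid10):
        cur = BinaryRange("sp", frozenset({1}))
        with pytest.raises(ValueError):
            apply_dispersal(cur, cur, "teleport", grid10)


class TestOccurrenceFilter:
    def test_threshold_inclusive(self):
        occ = np.zeros((2, 30), dtype=bool)
        occ[0, :19] = True
        occ[1, :20] = True
        pm = min_occurrence_filter(PresenceMatrix(occ, ["a", "b"]), min_occ=20)
        assert pm.species == ["b"]

    def test_identity_and_empty(self):
        occ = np.ones((3, 25), dtype=bool)
        pm = PresenceMatrix(occ, ["a", "b", "c"])
        assert min_occurrence_filter(pm, 20).species == ["a", "b", "c"]
        empty = PresenceMatrix(np.zeros((0, 25), dtype=bool), [])
        assert min_occurrence_filter(empty, 20).n_species == 0


class TestModelSpecies:
    def test_end_to_end_single_species(self, small_landscape):
        land = small_landscape
        sp = land.presences.species[0]
        res = model_species(sp, land.presences.cells_of(sp), land.climate,
                            land.future_climate, land.grid, seed=0,
                            n_repeats=4)
        assert len(res.evaluations) == 4
        if res.modellable:
            assert res.current.cells <= set(range(land.grid.n_cells))
            assert res.future["none"].cells <= res.future["limited"].cells
            assert res.future["limited"].cells <= res.future["full"].cells

    def test_pseudo_absences_avoid_presences(self):
        occ = np.arange(10)
        absences = sample_pseudo_absences(occ, 50, ratio=1.0, seed=0)
        assert not set(absences) & set(occ)
        assert absences.size == 10
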