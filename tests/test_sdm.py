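"""Maxent fitting, evaluation, thresholding and projection.

The fit is checked against the maximum-entropy stationarity condition (at
zero penalty the model's feature expectations equal the presence means), a
brute-force 1-D likelihood search, and the L1 KKT gap; AUC and threshold
selection are checked against exhaustive pairwise/candidate enumeration.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import logsumexp

from rangeshift.errors import (
    DegenerateFeatureError,
    EligibilityError,
    SchemaError,
)
from rangeshift.grids import CLIMATE_VARS, ClimateStack, SuitabilityMap
from rangeshift.sdm import (
    auc_score,
    binarize,
    default_regularization,
    fit_maxent,
    fit_species,
    project,
    replicate_evaluate,
    select_threshold,
    standardize_features,
)
from rangeshift.synthetic import BASELINE, make_climate_stack


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def auc_by_enumeration(pres, bg):
    """Pairwise concordance: wins + half-ties over all presence x bg pairs."""
    wins = sum(1.0 if p > b else 0.5 if p == b else 0.0
               for p in pres for b in bg)
    return wins / (len(pres) * len(bg))


def threshold_by_exhaustion(pres, bg):
    """Exhaustive max of sensitivity+specificity over all candidate scores,
    ties broken toward the lower threshold."""
    pres, bg = np.asarray(pres), np.asarray(bg)
    best_t, best_v = None, -np.inf
    for t in np.unique(np.concatenate([pres, bg])):
        v = np.mean(pres >= t) + np.mean(bg < t)
        if v > best_v + 1e-12:
            best_v, best_t = v, t
    return best_t


def occ_frame(stack, cells, species="sp1"):
    grid = stack.grid
    rows, cols = np.unravel_index(np.asarray(cells), grid.shape)
    return pd.DataFrame({
        "species": species,
        "lon": grid.origin_lon + (cols + 0.5) * grid.cell_size,
        "lat": grid.origin_lat - (rows + 0.5) * grid.cell_size,
    })


# ---------------------------------------------------------------------------
# features
# ---------------------------------------------------------------------------

class TestStandardizeFeatures:
    def test_ten_features_scaled_to_unit_range(self, small_stack):
        occ = occ_frame(small_stack, np.arange(0, 120, 10))
        pres_F, bg_F, scaling, pc, bc = standardize_features(
            small_stack, occ, n_background=200, seed=0)
        assert pres_F.shape == (12, 10)
        assert bg_F.shape == (200, 10)
        assert bg_F[:, :5].min() == pytest.approx(0.0)
        assert bg_F[:, :5].max() == pytest.approx(1.0)
        # quadratic features are squares of the linear ones
        np.testing.assert_allclose(bg_F[:, 5:], bg_F[:, :5] ** 2)

    def test_minmax_then_square(self):
        from rangeshift.sdm import FeatureScaling

        sc = FeatureScaling(mins=np.zeros(5), maxs=np.full(5, 10.0))
        f = sc.transform(np.full((1, 5), 5.0))
        np.testing.assert_allclose(f[0, :5], 0.5)
        np.testing.assert_allclose(f[0, 5:], 0.25)

    def test_nine_distinct_cells_ineligible(self, small_stack):
        occ = occ_frame(small_stack, list(range(9)) + [3, 4])  # 9 distinct
        with pytest.raises(EligibilityError):
            standardize_features(small_stack, occ, seed=0)

    def test_constant_layer_names_variable(self, small_grid):
        layers = {v: np.random.default_rng(0).normal(size=small_grid.shape)
                  for v in CLIMATE_VARS}
        layers["temp_seasonality"] = np.full(small_grid.shape, 5.0)
        layers["elevation"] = np.zeros(small_grid.shape)
        stack = ClimateStack(grid=small_grid, layers=layers)
        occ = occ_frame(stack, np.arange(0, 100, 10))
        with pytest.raises(DegenerateFeatureError, match="temp_seasonality"):
            standardize_features(stack, occ, seed=0)


# ---------------------------------------------------------------------------
# maxent fit
# ---------------------------------------------------------------------------

class TestFitMaxent:
    def test_no_signal_shrinks_to_zero(self):
        """Presences drawn identically to background + any positive penalty
        leave all weights at zero and q uniform."""
        rng = np.random.default_rng(0)
        bg = rng.uniform(size=(300, 4))
        pres = bg[rng.choice(300, 40, replace=False)]
        # give the presence sample the exact background feature means so the
        # no-information optimum is exactly lambda = 0
        pres = np.vstack([pres, bg])  # means pulled to background
        lam = fit_maxent(pres, bg, regularization=0.05)
        assert np.count_nonzero(lam) <= 1
        assert np.max(np.abs(lam)) < 0.2

    def test_zero_reg_matches_presence_means(self):
        """Maxent stationarity: at reg 0, E_q[f] equals the presence mean."""
        rng = np.random.default_rng(1)
        bg = rng.uniform(size=(200, 3))
        pres = bg[bg[:, 0] > 0.6][:30]
        lam = fit_maxent(pres, bg, regularization=0.0)
        q = np.exp(bg @ lam - logsumexp(bg @ lam))
        np.testing.assert_allclose(q @ bg, pres.mean(axis=0), atol=1e-6)

    def test_kkt_gap_bounded_by_penalty(self):
        """L1 stationarity: |E_q[f] - mean_pres[f]| <= reg per feature."""
        rng = np.random.default_rng(2)
        bg = rng.uniform(size=(250, 5))
        pres = bg[bg[:, 1] + bg[:, 3] > 1.1][:40]
        reg = np.array([0.02, 0.05, 0.01, 0.04, 0.03])
        lam = fit_maxent(pres, bg, regularization=reg)
        q = np.exp(bg @ lam - logsumexp(bg @ lam))
        gap = np.abs(q @ bg - pres.mean(axis=0))
        assert np.all(gap <= reg + 1e-6)

    def test_one_feature_matches_brute_force(self):
        """30-cell toy problem: penalized likelihood maximum vs a dense grid
        search over the single weight."""
        rng = np.random.default_rng(3)
        bg = rng.uniform(size=(30, 1))
        pres = bg[bg[:, 0] > 0.5][:12]
        reg = 0.01
        pres_mean = pres.mean()

        grid = np.linspace(-20, 20, 400001)
        vals = (pres_mean * grid
                - logsumexp(bg[:, 0:1] * grid[None, :], axis=0)
                - reg * np.abs(grid))
        oracle = grid[np.argmax(vals)]
        lam = fit_maxent(pres, bg, regularization=reg)
        assert lam[0] == pytest.approx(oracle, abs=1e-3)

    def test_negative_regularization_rejected(self):
        with pytest.raises(SchemaError):
            fit_maxent(np.zeros((12, 2)), np.zeros((20, 2)) + 0.5,
                       regularization=-1.0)

    def test_schedule_decays_with_sample_size(self):
        bg = np.random.default_rng(0).uniform(size=(100, 4))
        r10 = default_regularization(bg, 10)
        r100 = default_regularization(bg, 100)
        assert np.all(r100 < r10)


# ---------------------------------------------------------------------------
# AUC
# ---------------------------------------------------------------------------

class TestAuc:
    def test_perfect_ranking(self):
        assert auc_score(np.array([0.9, 0.8]), np.array([0.2, 0.1])) == 1.0

    def test_all_ties_give_half(self):
        assert auc_score(np.full(5, 0.3), np.full(9, 0.3)) == 0.5

    def test_enumerated_example(self):
        assert auc_score(np.array([0.9, 0.4]),
                         np.array([0.5, 0.1])) == pytest.approx(0.75)

    @given(st.lists(st.integers(0, 9), min_size=2, max_size=15),
           st.lists(st.integers(0, 9), min_size=2, max_size=15))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_matches_pairwise_enumeration(self, pres, bg):
        pres, bg = np.array(pres, float) / 10, np.array(bg, float) / 10
        assert auc_score(pres, bg) == pytest.approx(
            auc_by_enumeration(pres, bg))

    @given(st.lists(st.integers(0, 19), min_size=3, max_size=12),
           st.lists(st.integers(0, 19), min_size=3, max_size=12))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_invariant_under_monotone_transform(self, pres, bg):
        # well-separated score levels so strictly monotone transforms cannot
        # merge distinct values through rounding
        pres = (np.array(pres, float) + 1) / 21
        bg = (np.array(bg, float) + 1) / 21
        base = auc_score(pres, bg)
        for f in (lambda x: 3 * x + 1, np.log, lambda x: x**3):
            assert auc_score(f(pres), f(bg)) == pytest.approx(base)


# ---------------------------------------------------------------------------
# threshold
# ---------------------------------------------------------------------------

class TestSelectThreshold:
    def test_separable_example_returns_lowest_max_candidate(self):
        assert select_threshold(np.array([0.8, 0.7]),
                                np.array([0.3, 0.2])) == pytest.approx(0.7)

    def test_identical_sets_give_tss_zero(self):
        s = np.array([0.2, 0.5, 0.9])
        t = select_threshold(s, s)
        tss = np.mean(s >= t) + np.mean(s < t) - 1
        assert tss == pytest.approx(0.0)

    def test_empty_side_rejected(self):
        with pytest.raises(SchemaError):
            select_threshold(np.array([]), np.array([0.1]))

    @given(st.lists(st.integers(0, 19), min_size=2, max_size=20),
           st.lists(st.integers(0, 19), min_size=2, max_size=20))
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_matches_exhaustive_oracle(self, pres, bg):
        pres = np.array(pres, float) / 20
        bg = np.array(bg, float) / 20
        assert select_threshold(pres, bg) == pytest.approx(
            threshold_by_exhaustion(pres, bg))


# ---------------------------------------------------------------------------
# replicated evaluation, projection, binarization
# ---------------------------------------------------------------------------

class TestReplicatesAndProjection:
    def test_skipped_replicates_warn_not_silent(self, small_stack):
        occ = occ_frame(small_stack, np.arange(0, 100, 10))
        with pytest.warns(UserWarning, match="fewer than 2 validation"):
            with pytest.raises(EligibilityError):
                replicate_evaluate(small_stack, occ, n_replicates=2,
                                   split_ratio=0.95, seed=0)

    def test_future_equal_baseline_projects_identically(self, small_stack):
        occ = occ_frame(small_stack, np.arange(0, 240, 16))
        fit = fit_species(small_stack, occ, n_replicates=4, seed=1)
        a = project(fit, small_stack)
        b = project(fit, small_stack)
        np.testing.assert_array_equal(a.values, b.values)

    def test_projection_monotone_in_ensemble_score(self, small_stack):
        occ = occ_frame(small_stack, np.arange(0, 240, 16))
        fit = fit_species(small_stack, occ, n_replicates=4, seed=1)
        s = project(fit, small_stack)
        assert s.values.min() >= 0 and s.values.max() <= 1
        assert 0 < fit.threshold < 1
        assert len(fit.replicate_aucs) == 4

    def test_all_zero_weights_give_constant_surface(self, small_stack):
        occ = occ_frame(small_stack, np.arange(0, 240, 16))
        fit = fit_species(small_stack, occ, n_replicates=2, seed=1)
        for rep in fit.replicates:
            rep.weights = np.zeros_like(rep.weights)
            rep.center = 0.0
        s = project(fit, small_stack)
        assert np.unique(s.values).size == 1
        assert s.values.flat[0] == pytest.approx(0.5)

    def test_binarize_uses_geq_convention(self, small_grid):
        values = np.zeros(small_grid.shape)
        values[0, :3] = [0.4, 0.5, 0.6]
        s = SuitabilityMap("sp", "b", small_grid, values)
        r = binarize(s, 0.5)
        assert r.presence[0, :3].tolist() == [False, True, True]

    def test_binarize_extreme_thresholds(self, small_grid):
        values = np.random.default_rng(0).uniform(0.2, 0.8, small_grid.shape)
        s = SuitabilityMap("sp", "b", small_grid, values)
        assert binarize(s, 0.9).area == 0
        assert binarize(s, 0.1).area == small_grid.n_cells

    def test_raising_threshold_never_adds_cells(self, small_grid):
        values = np.random.default_rng(1).uniform(size=small_grid.shape)
        s = SuitabilityMap("sp", "b", small_grid, values)
        prev = binarize(s, 0.1).presence
        for t in (0.3, 0.5, 0.7, 0.9):
            cur = binarize(s, t).presence
            assert not np.any(cur & ~prev)
            prev = cur

    def test_invalid_threshold_rejected(self, small_grid):
        s = SuitabilityMap("sp", "b", small_grid,
                           np.full(small_grid.shape, 0.5))
        with pytest.raises(SchemaError):
            binarize(s, 1.5)
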