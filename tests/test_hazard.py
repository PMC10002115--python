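"""Hazard modeling: training-set construction, RF tuning, the information-value
baseline, and ROC / frequency validation — all against independent oracles."""

import numpy as np
import pytest

from ecorisk.grid import CategoricalRaster, GridSpec, Raster
from ecorisk.hazard import (
    DisasterInventory,
    HazardModelConfig,
    SampleSet,
    extract_features,
    factor_interval_frequencies,
    information_value_map,
    predict_hazard,
    roc_auc,
    sample_negatives,
    split_inventory,
    tune_and_fit,
)
from ecorisk.synthetic import PlantedHazardModel, RegionConfig, generate_region


# ---------------------------------------------------------------------------
# split


class TestSplitInventory:
    def test_published_seventy_percent_split_size(self):
        train, hold = split_inventory(8528, 0.70, seed=0)
        assert len(train) == 5970
        assert len(hold) == 8528 - 5970 == 2558

    def test_exact_halves(self):
        train, hold = split_inventory(10, 0.5, seed=1)
        assert len(train) == 5 and len(hold) == 5

    def test_disjoint_exhaustive_reproducible(self):
        t1, h1 = split_inventory(100, 0.7, seed=42)
        t2, h2 = split_inventory(100, 0.7, seed=42)
        assert np.array_equal(t1, t2) and np.array_equal(h1, h2)
        assert len(set(t1) & set(h1)) == 0
        assert len(set(t1) | set(h1)) == 100

    def test_degenerate_fraction_rejected(self):
        with pytest.raises(ValueError):
            split_inventory(3, 0.01, seed=0)  # train size rounds to 0


# ---------------------------------------------------------------------------
# negative sampling


class TestSampleNegatives:
    def test_eligible_set_matches_brute_force(self):
        """10x10 grid of 30 m cells, one positive at the center, 150 m buffer:
        the sampler's support equals the exhaustive center-distance scan."""
        g = GridSpec(10, 10, 30.0, 0.0, 300.0)
        pos = DisasterInventory(np.array([[150.0, 150.0]]))
        xs, ys = g.cell_centers()
        oracle = np.hypot(xs - 150.0, ys - 150.0) >= 150.0
        n_eligible = int(oracle.sum())
        neg = sample_negatives(pos, g, None, n=n_eligible, buffer_m=150.0, seed=0)
        got = {tuple(p) for p in neg.coords.tolist()}
        expected = {
            (xs[r, c], ys[r, c]) for r, c in zip(*np.nonzero(oracle))
        }
        assert got == expected
        with pytest.raises(ValueError, match=str(n_eligible)):
            sample_negatives(pos, g, None, n=n_eligible + 1, buffer_m=150.0, seed=0)

    def test_no_positives_no_river_samples_anywhere(self):
        g = GridSpec(6, 6, 30.0, 0.0, 180.0)
        neg = sample_negatives(DisasterInventory(np.empty((0, 2))), g, None, n=36, seed=1)
        assert len(neg) == 36

    def test_min_distance_respects_buffer(self, small_region):
        inv = DisasterInventory(small_region.events_xy)
        neg = sample_negatives(
            inv, small_region.stack.grid, small_region.river_mask, n=100,
            buffer_m=100.0, seed=3,
        )
        from scipy.spatial import cKDTree

        d, _ = cKDTree(inv.coords).query(neg.coords, k=1)
        assert d.min() >= 100.0
        # river cells excluded
        g = small_region.stack.grid
        r, c = g.point_to_cell(neg.coords[:, 0], neg.coords[:, 1])
        assert np.all(small_region.river_mask.codes[r, c] == 0)


# ---------------------------------------------------------------------------
# feature extraction


class TestExtractFeatures:
    def test_lookup_matches_per_point_loop(self, small_region):
        rng = np.random.default_rng(0)
        g = small_region.stack.grid
        xs = rng.uniform(g.origin_x, g.origin_x + g.n_cols * g.cell_size, 100)
        ys = rng.uniform(g.origin_y - g.n_rows * g.cell_size, g.origin_y, 100)
        pts = np.column_stack([xs, ys])
        samples = extract_features(pts, small_region.stack)
        for i, (x, y) in enumerate(samples.coords):
            r, c = g.point_to_cell(np.array([x]), np.array([y]))
            for j, name in enumerate(samples.factor_names):
                layer = small_region.stack.layer(name)
                arr = layer.codes if isinstance(layer, CategoricalRaster) else layer.values
                assert samples.features[i, j] == arr[r[0], c[0]]

    def test_outside_points_dropped_and_counted(self, small_region):
        g = small_region.stack.grid
        inside = np.array([[g.origin_x + 45.0, g.origin_y - 45.0]])
        outside = np.array([[g.origin_x - 1e4, g.origin_y + 1e4]])
        samples = extract_features(np.vstack([inside, outside]), small_region.stack)
        assert samples.features.shape[0] == 1
        assert samples.n_dropped == 1

    def test_all_points_outside_is_an_error(self, small_region):
        with pytest.raises(ValueError, match="outside"):
            extract_features(np.array([[0.0, 0.0]]), small_region.stack)


# ---------------------------------------------------------------------------
# random forest


def toy_separable_samples(n=120, seed=0) -> SampleSet:
    rng = np.random.default_rng(seed)
    n2 = n // 2
    feats = np.zeros((n, 9))
    feats[:, 0] = np.concatenate([rng.uniform(0, 0.4, n2), rng.uniform(0.6, 1.0, n2)])
    feats[:, 1] = np.concatenate([rng.uniform(0.6, 1.0, n2), rng.uniform(0, 0.4, n2)])
    feats[:, 2:] = rng.uniform(0, 1, (n, 7))
    labels = np.r_[np.zeros(n2, int), np.ones(n2, int)]
    return SampleSet(feats, labels, np.zeros((n, 2)))


class TestTuneAndFit:
    def test_separable_toy_reaches_perfect_cv(self):
        samples = toy_separable_samples()
        _, report = tune_and_fit(
            samples,
            HazardModelConfig(tuning_grid_trees=(50,), tuning_grid_features=(2,), seed=0),
        )
        assert all(s == 1.0 for s in report.cv_scores)
        assert report.chosen_n_trees == 50 and report.chosen_m_features == 2

    def test_importances_normalized_and_grid_complete(self):
        samples = toy_separable_samples()
        _, report = tune_and_fit(
            samples,
            HazardModelConfig(tuning_grid_trees=(25, 50), tuning_grid_features=(2, 4), seed=0),
        )
        assert sum(report.importances.values()) == pytest.approx(1.0)
        assert set(report.oob_error_grid) == {(25, 2), (25, 4), (50, 2), (50, 4)}
        chosen = (report.chosen_n_trees, report.chosen_m_features)
        assert report.oob_error_grid[chosen] == min(report.oob_error_grid.values())

    def test_single_class_rejected(self):
        s = toy_separable_samples()
        bad = SampleSet(s.features, np.ones(len(s.labels), int), s.coords)
        with pytest.raises(ValueError, match="both"):
            tune_and_fit(bad)

    def test_pure_noise_feature_ranks_below_planted_factors(self):
        """Append a uniform-noise column to planted synthetic samples: every
        truly weighted factor must outrank it in >= 8 of 10 seeds.  (Gini
        importance is cardinality-biased, so continuous noise can legitimately
        outrank low-cardinality categorical decoys; the informative factors
        are the meaningful comparison.)"""
        wins = 0
        for seed in range(10):
            region = generate_region(
                RegionConfig(grid=GridSpec(96, 96, 30.0, 0.0, 96 * 30.0, "EPSG:32650"), seed=seed),
                PlantedHazardModel(n_events=400),
            )
            inv = DisasterInventory(region.events_xy)
            neg = sample_negatives(
                inv, region.stack.grid, region.river_mask, n=400, buffer_m=60.0, seed=seed
            )
            pos_s = extract_features(inv, region.stack, 1)
            neg_s = extract_features(neg, region.stack, 0)
            s = SampleSet.concatenate(pos_s, neg_s)
            rng = np.random.default_rng(seed)
            feats = np.column_stack([s.features, rng.uniform(0, 1, len(s.labels))])
            aug = SampleSet(feats, s.labels, s.coords, (*s.factor_names, "noise"))
            _, report = tune_and_fit(
                aug, HazardModelConfig(tuning_grid_trees=(100,), tuning_grid_features=(5,), seed=seed)
            )
            planted = set(region.planted_model.factor_weights)
            noise_rank = report.importance_ranking().index("noise")
            wins += all(
                report.importance_ranking().index(f) < noise_rank for f in planted
            )
        assert wins >= 8


class TestPredictHazard:
    def test_probability_bounds_and_training_consistency(self, small_region):
        inv = DisasterInventory(small_region.events_xy)
        neg = sample_negatives(
            inv, small_region.stack.grid, small_region.river_mask, n=len(inv),
            buffer_m=60.0, seed=0,
        )
        samples = SampleSet.concatenate(
            extract_features(inv, small_region.stack, 1),
            extract_features(neg, small_region.stack, 0),
        )
        model, _ = tune_and_fit(
            samples, HazardModelConfig(tuning_grid_trees=(50,), tuning_grid_features=(5,), seed=0)
        )
        hz = predict_hazard(model, small_region.stack)
        vals = hz.raster.unmasked()
        assert np.all((vals >= 0) & (vals <= 1))
        # map restricted to sample cells equals per-sample predictions
        g = small_region.stack.grid
        per_sample = model.predict_proba(samples.features)[:, 1]
        r, c = g.point_to_cell(samples.coords[:, 0], samples.coords[:, 1])
        assert np.allclose(hz.raster.values[r, c], per_sample)


# ---------------------------------------------------------------------------
# information value


def iv_stack_one_factor(values: np.ndarray) -> "ConditioningStack":  # noqa: F821
    """A stack whose only informative factor is 'elevation'; the other eight
    are constant or single-class so they contribute zero information."""
    from ecorisk.synthetic import ConditioningStack

    g = GridSpec(values.shape[0], values.shape[1], 30.0, 0.0, values.shape[0] * 30.0, "T")
    const = Raster(g, np.zeros(g.shape))
    cat = CategoricalRaster(g, np.ones(g.shape, np.int64), {1: "only"})
    return ConditioningStack(
        elevation=Raster(g, values),
        slope=const.copy(), precipitation=const.copy(), ndvi=const.copy(),
        aspect=cat.copy(), landuse=cat.copy(), lithology=cat.copy(),
        dist_fault=const.copy(), dist_river=const.copy(),
    )


class TestInformationValue:
    def test_two_equal_bins_all_disasters_in_one(self):
        """One binary factor, equal-area bins, every disaster in bin 1:
        IV(bin 1) = ln 2 and IV(bin 2) is the half-count floor."""
        vals = np.zeros((10, 10))
        vals[:, 5:] = 1.0  # two equal halves
        stack = iv_stack_one_factor(vals)
        g = stack.grid
        # 8 disasters, all on the right (value-1) half
        xs = g.origin_x + (np.arange(8) % 5 + 5 + 0.5) * 30.0
        ys = g.origin_y - (np.arange(8) // 5 + 0.5) * 30.0
        inv = DisasterInventory(np.column_stack([xs, ys]))
        hz, tables = information_value_map(inv, stack, n_bins=2)
        tab = tables.tables["elevation"].set_index("bin")
        assert tab.loc[1, "iv"] == pytest.approx(np.log(2))
        assert tab.loc[0, "iv"] == pytest.approx(np.log((0.5 / 8) / 0.5))
        right = hz.raster.values[:, 5:]
        left = hz.raster.values[:, :5]
        assert np.allclose(right, right[0, 0]) and right[0, 0] > left[0, 0]

    def test_proportional_distribution_gives_flat_zero_map(self):
        vals = np.zeros((10, 10))
        vals[:, 5:] = 1.0
        stack = iv_stack_one_factor(vals)
        g = stack.grid
        # equal disaster shares on both halves -> zero information everywhere
        pts = np.array([
            [g.origin_x + 2.5 * 30, g.origin_y - 15.0],
            [g.origin_x + 7.5 * 30, g.origin_y - 15.0],
        ])
        hz, _ = information_value_map(DisasterInventory(pts), stack, n_bins=2)
        assert np.allclose(hz.raster.values, 0.0, atol=1e-12)

    def test_scale_invariance_under_count_doubling(self):
        """Doubling every count (cells and disasters alike) leaves the IV of
        every occupied bin unchanged — information values are pure ratios."""
        vals = np.zeros((10, 10)); vals[:, 5:] = 1.0
        stack1 = iv_stack_one_factor(vals)
        stack2 = iv_stack_one_factor(np.vstack([vals, vals]))
        g1, g2 = stack1.grid, stack2.grid

        def pts(g):
            # 3 disasters in the high bin, 1 in the low bin
            xs = g.origin_x + np.array([5.5, 6.5, 7.5, 1.5]) * 30.0
            ys = g.origin_y - 15.0 * np.ones(4)
            return np.column_stack([xs, ys])

        inv1 = DisasterInventory(pts(g1))
        p2 = pts(g2)
        inv2 = DisasterInventory(np.vstack([p2, p2 + [0.0, -10 * 30.0]]))
        _, t1 = information_value_map(inv1, stack1, n_bins=2)
        _, t2 = information_value_map(inv2, stack2, n_bins=2)
        assert np.allclose(
            t1.tables["elevation"]["iv"], t2.tables["elevation"]["iv"]
        )


# ---------------------------------------------------------------------------
# ROC / AUC


def auc_pair_oracle(pos, neg):
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def scores_as_map(pos_scores, neg_scores):
    """Embed score lists in a raster so roc_auc can look them up."""
    all_scores = np.concatenate([pos_scores, neg_scores])
    n = len(all_scores)
    g = GridSpec(1, n, 30.0, 0.0, 30.0, "T")
    raster = Raster(g, all_scores.reshape(1, n))
    from ecorisk.hazard import HazardMap

    xs = (np.arange(n) + 0.5) * 30.0
    ys = np.full(n, 15.0)
    pos_pts = np.column_stack([xs[: len(pos_scores)], ys[: len(pos_scores)]])
    neg_pts = np.column_stack([xs[len(pos_scores):], ys[len(pos_scores):]])
    return HazardMap(raster, "rf"), pos_pts, neg_pts


class TestRocAuc:
    def test_perfect_separation(self):
        hz, p, n = scores_as_map(np.array([0.9, 0.8]), np.array([0.2, 0.1]))
        auc, curve, dropped = roc_auc(hz, p, n)
        assert auc == 1.0 and dropped == 0

    def test_all_ties_give_half(self):
        hz, p, n = scores_as_map(np.full(4, 0.5), np.full(4, 0.5))
        auc, _, _ = roc_auc(hz, p, n)
        assert auc == 0.5

    def test_reference_eight_point_case(self):
        hz, p, n = scores_as_map(
            np.array([0.9, 0.8, 0.6, 0.4]), np.array([0.7, 0.5, 0.3, 0.2])
        )
        auc, _, _ = roc_auc(hz, p, n)
        assert auc == pytest.approx(13 / 16)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_pair_count(self, seed):
        rng = np.random.default_rng(seed)
        pos = np.round(rng.uniform(0, 1, rng.integers(3, 25)), 2)
        neg = np.round(rng.uniform(0, 1, rng.integers(3, 25)), 2)
        hz, p, n = scores_as_map(pos, neg)
        auc, _, _ = roc_auc(hz, p, n)
        assert auc == pytest.approx(auc_pair_oracle(pos, neg))


# ---------------------------------------------------------------------------
# factor interval frequencies


class TestFactorIntervalFrequencies:
    def test_concentration_in_one_interval(self, small_region):
        elev = small_region.stack.elevation
        g = elev.grid
        lo = float(elev.values.min())
        # all points at the single lowest cell
        r, c = np.unravel_index(np.argmin(elev.values), elev.values.shape)
        pt = [[g.origin_x + (c + 0.5) * g.cell_size, g.origin_y - (r + 0.5) * g.cell_size]]
        table = factor_interval_frequencies(
            elev, [(lo - 1, lo + 1), (lo + 1, 1e5)], np.array(pt * 7)
        )
        assert table["count"].tolist() == [7, 0]
        assert table["frequency_per_100km2"].iloc[1] == 0.0

    def test_single_interval_collapses_to_totals(self, small_region):
        elev = small_region.stack.elevation
        pts = small_region.events_xy
        table = factor_interval_frequencies(
            elev, [(-1.0, float(elev.values.max()))], pts
        )
        assert len(table) == 1
        assert table["count"].iloc[0] == len(pts)
        g = elev.grid
        assert table["area_km2"].iloc[0] == pytest.approx(g.n_rows * g.n_cols * g.cell_area_km2)

    def test_overlapping_intervals_rejected(self, small_region):
        with pytest.raises(ValueError, match="overlap"):
            factor_interval_frequencies(
                small_region.stack.elevation, [(0, 10), (5, 20)], small_region.events_xy
            )

    def test_categorical_factor_uses_class_bins(self, small_region):
        table = factor_interval_frequencies(
            small_region.stack.landuse, None, small_region.events_xy
        )
        assert set(table["interval"]) == set(small_region.stack.landuse.legend.values())
        assert table["count"].sum() == len(small_region.events_xy)
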