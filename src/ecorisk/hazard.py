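"""Geological-disaster hazard modeling.

Workflow: split the disaster inventory into training/validation points, draw
non-disaster (negative) samples outside a buffer around every disaster point
and off river cells, extract the nine conditioning-factor values at each
sample, fit a random-forest classifier tuned by out-of-bag error over a
(n_trees, m_features) grid, and map the per-cell disaster probability.  A
bivariate information-value model provides the classical baseline, and
validation uses ROC/AUC plus frequency-ratio analysis of the classified map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold, cross_val_score

from .geodata import FrequencyTable, jenks_breaks
from .grid import CategoricalRaster, GridSpec, Raster
from .synthetic import ConditioningStack, FACTOR_NAMES

__all__ = [
    "DisasterInventory",
    "SampleSet",
    "HazardModelConfig",
    "HazardModelReport",
    "HazardMap",
    "split_inventory",
    "sample_negatives",
    "extract_features",
    "tune_and_fit",
    "predict_hazard",
    "information_value_map",
    "roc_auc",
    "factor_interval_frequencies",
]


@dataclass
class DisasterInventory:
    """Point inventory of historical geological disasters."""

    coords: np.ndarray  # (n, 2) x, y in grid CRS meters
    types: list[str | None] = None  # type: ignore[assignment]
    provenance: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, float).reshape(-1, 2)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("inventory coordinates must be finite")
        if self.types is None:
            self.types = [None] * len(self.coords)
        n_dup = len(self.coords) - len({tuple(p) for p in self.coords.tolist()})
        if n_dup:
            warnings.warn(f"inventory contains {n_dup} duplicate points", stacklevel=2)

    def __len__(self) -> int:
        return len(self.coords)

    def subset(self, indices: np.ndarray) -> "DisasterInventory":
        return DisasterInventory(
            self.coords[indices],
            [self.types[i] for i in np.asarray(indices)],
            self.provenance,
        )


@dataclass
class SampleSet:
    """Feature matrix of disaster / non-disaster samples in factor order."""

    features: np.ndarray  # (n, 9)
    labels: np.ndarray  # 1 = disaster, 0 = background
    coords: np.ndarray  # (n, 2)
    factor_names: tuple[str, ...] = FACTOR_NAMES
    n_dropped: int = 0  # points lost to nodata / outside-extent

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, float)
        self.labels = np.asarray(self.labels, int)
        self.coords = np.asarray(self.coords, float).reshape(-1, 2)
        n = self.features.shape[0]
        if self.labels.shape[0] != n or self.coords.shape[0] != n:
            raise ValueError("features, labels and coords must align")

    @property
    def label_balance(self) -> tuple[int, int]:
        return int(np.sum(self.labels == 0)), int(np.sum(self.labels == 1))

    @staticmethod
    def concatenate(a: "SampleSet", b: "SampleSet") -> "SampleSet":
        return SampleSet(
            np.vstack([a.features, b.features]),
            np.concatenate([a.labels, b.labels]),
            np.vstack([a.coords, b.coords]),
            a.factor_names,
            a.n_dropped + b.n_dropped,
        )


@dataclass(frozen=True)
class HazardModelConfig:
    """Random-forest configuration and tuning grid.

    The operating point (100 trees, 5 features per split) is the default; the
    grid search may confirm or overrule it by out-of-bag error.
    """

    n_trees: int = 100
    m_features: int = 5
    tuning_grid_trees: tuple[int, ...] = (50, 100, 200)
    tuning_grid_features: tuple[int, ...] = (3, 5, 7)
    cv_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if not 1 <= self.m_features <= len(FACTOR_NAMES):
            raise ValueError(f"m_features must be in [1, {len(FACTOR_NAMES)}]")


@dataclass
class HazardModelReport:
    """Outcome of the grid search, cross-validation and importance analysis."""

    chosen_n_trees: int
    chosen_m_features: int
    oob_error_grid: dict[tuple[int, int], float]
    cv_scores: tuple[float, ...]
    importances: dict[str, float]  # normalized mean impurity decrease, sums to 1
    seed: int

    def importance_ranking(self) -> list[str]:
        """Factor names, most important first."""
        return sorted(self.importances, key=self.importances.get, reverse=True)


@dataclass
class HazardMap:
    """Continuous hazard surface: a probability for RF, a score for the
    information-value model (unbounded, flagged by ``is_probability``)."""

    raster: Raster
    model_tag: str  # "rf" or "information_value"

    @property
    def is_probability(self) -> bool:
        return self.model_tag == "rf"


# ---------------------------------------------------------------------------
# training-set construction


def split_inventory(
    n_total: int, train_fraction: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Random train/holdout index split; train size is round-half-up of
    n_total * train_fraction.  Disjoint, exhaustive, seed-reproducible."""
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    n_train = int(np.floor(n_total * train_fraction + 0.5))
    if n_train == 0 or n_train == n_total:
        raise ValueError(
            f"split of {n_total} at {train_fraction} leaves an empty side ({n_train} train)"
        )
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    perm = rng.permutation(n_total)
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


def sample_negatives(
    positives: DisasterInventory,
    grid: GridSpec,
    river_mask: CategoricalRaster | None,
    n: int,
    buffer_m: float = 500.0,
    seed: int = 0,
    nodata_mask: np.ndarray | None = None,
) -> DisasterInventory:
    """Sample ``n`` non-disaster points from eligible cells.

    A cell is eligible when its center lies at least ``buffer_m`` from every
    disaster point, it is not a river cell, and it is not nodata.  Cells are
    drawn uniformly without replacement; returned points are cell centers.
    """
    xs, ys = grid.cell_centers()
    eligible = np.ones(grid.shape, dtype=bool)
    if nodata_mask is not None:
        eligible &= ~nodata_mask
    if river_mask is not None:
        if river_mask.grid != grid:
            raise ValueError("river mask is not co-registered with the sampling grid")
        eligible &= river_mask.codes == 0
    if len(positives) > 0:
        tree = cKDTree(positives.coords)
        dist, _ = tree.query(np.column_stack([xs.ravel(), ys.ravel()]), k=1)
        eligible &= (dist.reshape(grid.shape) >= buffer_m)
    n_eligible = int(eligible.sum())
    if n_eligible < n:
        raise ValueError(f"only {n_eligible} eligible cells for {n} requested negatives")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 211]))
    flat = np.nonzero(eligible.ravel())[0]
    chosen = rng.choice(flat, size=n, replace=False)
    rows, cols = np.unravel_index(chosen, grid.shape)
    return DisasterInventory(
        np.column_stack([xs[rows, cols], ys[rows, cols]]),
        provenance=f"sampled negatives (buffer {buffer_m} m, seed {seed})",
    )


def extract_features(
    points: DisasterInventory | np.ndarray,
    stack: ConditioningStack,
    label: int = 1,
) -> SampleSet:
    """Extract the nine factor values at each point's cell.

    Points outside the extent or on nodata cells are dropped and counted in
    ``n_dropped``; if every point drops, an error is raised.
    """
    coords = points.coords if isinstance(points, DisasterInventory) else np.asarray(points, float)
    coords = coords.reshape(-1, 2)
    grid = stack.grid
    row, col = grid.point_to_cell(coords[:, 0], coords[:, 1])
    inside = grid.contains(row, col)
    mask = stack.nodata_mask()
    keep = inside.copy()
    keep[inside] &= ~mask[row[inside], col[inside]]
    n_dropped = int((~keep).sum())
    if keep.sum() == 0:
        raise ValueError("every point fell outside the grid or on nodata")
    row, col = row[keep], col[keep]
    cols = []
    for name in FACTOR_NAMES:
        layer = stack.layer(name)
        arr = layer.codes if isinstance(layer, CategoricalRaster) else layer.values
        cols.append(np.asarray(arr, float)[row, col])
    return SampleSet(
        np.column_stack(cols),
        np.full(row.size, label, dtype=int),
        coords[keep],
        FACTOR_NAMES,
        n_dropped,
    )


# ---------------------------------------------------------------------------
# random forest


def tune_and_fit(
    samples: SampleSet, config: HazardModelConfig = HazardModelConfig()
) -> tuple[RandomForestClassifier, HazardModelReport]:
    """Grid-search (n_trees, m_features) by OOB error, then fit and report.

    Ties in OOB error go to fewer trees, then fewer features.  The report
    carries the 5-fold cross-validated accuracies and the normalized mean
    impurity decrease per factor.
    """
    classes = np.unique(samples.labels)
    if classes.size < 2:
        raise ValueError("training set must contain both disaster and background samples")
    n = samples.features.shape[0]
    if n < 10 * config.cv_folds:
        raise ValueError(f"need at least {10 * config.cv_folds} samples, got {n}")

    oob_grid: dict[tuple[int, int], float] = {}
    best: tuple[int, int] | None = None
    for n_trees in sorted(set(config.tuning_grid_trees)):
        for m_feat in sorted(set(config.tuning_grid_features)):
            rf = RandomForestClassifier(
                n_estimators=n_trees,
                max_features=m_feat,
                oob_score=True,
                random_state=config.seed,
                n_jobs=1,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # tiny sets can miss OOB coverage
                rf.fit(samples.features, samples.labels)
            err = 1.0 - float(rf.oob_score_)
            oob_grid[(n_trees, m_feat)] = err
            if best is None or err < oob_grid[best]:
                best = (n_trees, m_feat)

    n_trees, m_feat = best
    model = RandomForestClassifier(
        n_estimators=n_trees,
        max_features=m_feat,
        oob_score=True,
        random_state=config.seed,
        n_jobs=1,
    )
    cv = StratifiedKFold(n_splits=config.cv_folds, shuffle=True, random_state=config.seed)
    cv_scores = cross_val_score(
        model, samples.features, samples.labels, cv=cv, scoring="accuracy", n_jobs=1
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(samples.features, samples.labels)

    importances = dict(zip(samples.factor_names, model.feature_importances_))
    report = HazardModelReport(
        chosen_n_trees=n_trees,
        chosen_m_features=m_feat,
        oob_error_grid=oob_grid,
        cv_scores=tuple(float(s) for s in cv_scores),
        importances=importances,
        seed=config.seed,
    )
    return model, report


def predict_hazard(model: RandomForestClassifier, stack: ConditioningStack) -> HazardMap:
    """Per-cell disaster probability over the whole stack; nodata propagated."""
    features, idx = stack.feature_matrix()
    prob = model.predict_proba(features)[:, list(model.classes_).index(1)]
    out = np.full(stack.grid.shape, np.nan).ravel()
    out[idx] = prob
    mask = stack.nodata_mask()
    return HazardMap(Raster(stack.grid, out.reshape(stack.grid.shape), mask), "rf")


# ---------------------------------------------------------------------------
# information-value baseline


@dataclass
class InformationValueTables:
    """Per-factor bin edges / codes and information values."""

    tables: dict[str, pd.DataFrame] = field(default_factory=dict)


def information_value_map(
    positives: DisasterInventory,
    stack: ConditioningStack,
    n_bins: int = 8,
    floor_count: float = 0.5,
) -> tuple[HazardMap, InformationValueTables]:
    """Bivariate information-value hazard score.

    For factor j with bins i: IV_ij = ln[(N_ij / N) / (S_ij / S)] where N is
    the total disaster count, N_ij disasters in the bin, S the unmasked cell
    count and S_ij the bin's cell count.  A cell's score is the sum of its
    bins' IVs over all nine factors.  Continuous factors are binned by natural
    breaks (``n_bins``); categorical factors use one bin per class.  Bins with
    zero disasters get the half-count continuity floor
    IV = ln[(floor_count/N) / (S_ij/S)] instead of -inf.
    """
    grid = stack.grid
    mask = stack.nodata_mask()
    row, col = grid.point_to_cell(positives.coords[:, 0], positives.coords[:, 1])
    inside = grid.contains(row, col)
    row, col = row[inside], col[inside]
    keep = ~mask[row, col]
    row, col = row[keep], col[keep]
    n_events = row.size
    if n_events == 0:
        raise ValueError("no disaster points fall on valid cells")
    s_total = int((~mask).sum())

    score = np.zeros(grid.shape)
    tables = InformationValueTables()
    for name in FACTOR_NAMES:
        layer = stack.layer(name)
        if isinstance(layer, CategoricalRaster):
            vals = layer.codes
            bin_ids = vals.copy()
            bin_keys = np.unique(vals[~mask])
        else:
            vals = layer.values
            k = min(n_bins, _distinct(vals[~mask], n_bins))
            if k < 2:  # constant factor: a single bin carries no information
                bin_ids = np.zeros(vals.shape, dtype=np.int64)
                bin_keys = np.array([0])
            else:
                edges = jenks_breaks(_subsample(vals[~mask], 10_000, 977), k)
                bin_ids = np.digitize(vals, edges, right=True)
                bin_keys = np.arange(len(edges) + 1)

        iv_by_bin: dict[int, float] = {}
        rows = []
        event_bins = bin_ids[row, col]
        for b in bin_keys:
            s_ij = int(np.sum((bin_ids == b) & ~mask))
            if s_ij == 0:
                raise ValueError(f"factor {name!r}: bin {b} has zero cells (degenerate binning)")
            n_ij = int(np.sum(event_bins == b))
            n_eff = n_ij if n_ij > 0 else floor_count
            iv = float(np.log((n_eff / n_events) / (s_ij / s_total)))
            iv_by_bin[int(b)] = iv
            rows.append({"bin": int(b), "cells": s_ij, "events": n_ij, "iv": iv})
        tables.tables[name] = pd.DataFrame(rows)
        lut = np.zeros(int(bin_ids.max()) + 1)
        for b, iv in iv_by_bin.items():
            lut[b] = iv
        score += lut[np.clip(bin_ids, 0, len(lut) - 1)]

    score_arr = score.copy()
    score_arr[mask] = np.nan
    return HazardMap(Raster(grid, score_arr, mask.copy()), "information_value"), tables


def _subsample(vals: np.ndarray, cap: int, seed: int) -> np.ndarray:
    if vals.size <= cap:
        return vals
    return np.random.default_rng(seed).choice(vals, size=cap, replace=False)


def _distinct(vals: np.ndarray, cap: int) -> int:
    return min(cap, np.unique(vals).size)


# ---------------------------------------------------------------------------
# validation


def roc_auc(
    hazard_map: HazardMap,
    positives: np.ndarray,
    negatives: np.ndarray,
) -> tuple[float, pd.DataFrame, int]:
    """ROC analysis of a hazard surface against held-out points.

    Scores are looked up at each point's cell; points on nodata or outside
    the extent are dropped (count returned).  AUC is the rank (Mann–Whitney)
    statistic with tie correction.  Returns (auc, curve, n_dropped) with the
    curve as columns fpr/tpr/threshold.
    """
    raster = hazard_map.raster
    grid = raster.grid

    def _scores(points: np.ndarray) -> tuple[np.ndarray, int]:
        pts = np.asarray(points, float).reshape(-1, 2)
        row, col = grid.point_to_cell(pts[:, 0], pts[:, 1])
        ok = grid.contains(row, col)
        row, col = row[ok], col[ok]
        valid = ~raster.nodata_mask[row, col]
        return raster.values[row[valid], col[valid]], int(pts.shape[0] - valid.sum())

    pos_scores, d1 = _scores(positives)
    neg_scores, d2 = _scores(negatives)
    if pos_scores.size == 0 or neg_scores.size == 0:
        raise ValueError("both point sets must retain at least one valid point")
    y = np.concatenate([np.ones(pos_scores.size), np.zeros(neg_scores.size)])
    s = np.concatenate([pos_scores, neg_scores])
    auc = float(roc_auc_score(y, s))
    fpr, tpr, thr = roc_curve(y, s)
    curve = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    return auc, curve, d1 + d2


def factor_interval_frequencies(
    factor: Raster | CategoricalRaster,
    intervals: Sequence[tuple[float, float]] | None,
    points: np.ndarray,
) -> pd.DataFrame:
    """Disaster frequency per factor interval (area-normalized, per 100 km^2).

    ``intervals`` are lower-open/upper-closed (lo, hi] pairs that must not
    overlap; pass ``None`` for a categorical factor to use one interval per
    class.  Columns: interval label, area_km2, count, frequency_per_100km2.
    """
    grid = factor.grid
    pts = np.asarray(points, float).reshape(-1, 2)
    row, col = grid.point_to_cell(pts[:, 0], pts[:, 1])
    ok = grid.contains(row, col)
    row, col = row[ok], col[ok]
    valid = ~factor.nodata_mask[row, col]
    row, col = row[valid], col[valid]

    rows = []
    if isinstance(factor, CategoricalRaster):
        point_vals = factor.codes[row, col]
        for code in sorted(factor.legend):
            in_zone = (factor.codes == code) & ~factor.nodata_mask
            area = float(in_zone.sum()) * grid.cell_area_km2
            count = int(np.sum(point_vals == code))
            rows.append(
                {
                    "interval": factor.legend[code],
                    "area_km2": area,
                    "count": count,
                    "frequency_per_100km2": 100.0 * count / area if area > 0 else np.nan,
                }
            )
        return pd.DataFrame(rows)

    if intervals is None:
        raise ValueError("continuous factors require explicit intervals")
    ivs = sorted((float(lo), float(hi)) for lo, hi in intervals)
    for (lo1, hi1), (lo2, _) in zip(ivs, ivs[1:]):
        if lo2 < hi1:
            raise ValueError(f"intervals overlap: ({lo1}, {hi1}] and ({lo2}, ...]")
    point_vals = factor.values[row, col]
    for lo, hi in ivs:
        in_zone = (factor.values > lo) & (factor.values <= hi) & ~factor.nodata_mask
        area = float(in_zone.sum()) * grid.cell_area_km2
        count = int(np.sum((point_vals > lo) & (point_vals <= hi)))
        rows.append(
            {
                "interval": f"({lo:g}, {hi:g}]",
                "area_km2": area,
                "count": count,
                "frequency_per_100km2": 100.0 * count / area if area > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def hazard_frequency_table(
    classified_map, inventory: DisasterInventory
) -> FrequencyTable:
    """Frequency-ratio validation table of a classified hazard map."""
    from .geodata import frequency_table

    return frequency_table(classified_map, inventory.coords)
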