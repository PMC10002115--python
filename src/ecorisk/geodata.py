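"""Shared raster operations: resampling, range standardization, natural-breaks
classification, distance-to-feature rasters, and frequency tables.

These are the primitives every assessment stage (hazard, vulnerability, damage,
risk) leans on.  The natural-breaks classifier is an exact Fisher–Jenks dynamic
program; on large rasters the breaks are computed on a seeded subsample and
applied to all cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage
from shapely.geometry import LineString, MultiLineString, box

from .grid import CategoricalRaster, ClassifiedMap, GridSpec, LEVEL_LABELS, Raster

__all__ = [
    "resample_to_grid",
    "range_standardize",
    "jenks_breaks",
    "jenks_breaks_raster",
    "classify",
    "distance_raster",
    "FrequencyTable",
    "frequency_table",
]


# ---------------------------------------------------------------------------
# resampling

_RESAMPLE_ORDER = {"nearest": 0, "bilinear": 1, "cubic": 3}


def resample_to_grid(
    raster: Raster | CategoricalRaster,
    target: GridSpec,
    method: str = "cubic",
) -> Raster | CategoricalRaster:
    """Resample a raster onto ``target`` by sampling at target cell centers.

    ``method`` is one of ``nearest``, ``bilinear``, ``cubic`` (cubic
    convolution is the default for continuous layers).  Categorical layers
    must use ``nearest`` — interpolation would invent classes.  Source and
    target CRS must match.
    """
    if method not in _RESAMPLE_ORDER:
        raise ValueError(f"unknown method {method!r}; choose from {sorted(_RESAMPLE_ORDER)}")
    if raster.grid.crs_tag != target.crs_tag:
        raise ValueError(
            f"CRS mismatch: source {raster.grid.crs_tag!r} vs target {target.crs_tag!r}"
        )
    categorical = isinstance(raster, CategoricalRaster)
    if categorical and method != "nearest":
        raise ValueError("categorical rasters must be resampled with method='nearest'")
    if raster.grid == target:
        return raster.copy()

    src = raster.grid
    tx, ty = target.cell_centers()
    # fractional (row, col) position of each target center in the source array
    col_f = (tx - src.origin_x) / src.cell_size - 0.5
    row_f = (src.origin_y - ty) / src.cell_size - 0.5
    coords = np.stack([row_f.ravel(), col_f.ravel()])

    near = ndimage.map_coordinates(
        np.asarray(raster.codes if categorical else raster.values, float),
        coords, order=0, mode="nearest",
    ).reshape(target.shape)
    mask = ndimage.map_coordinates(
        raster.nodata_mask.astype(np.uint8), coords, order=0, mode="nearest"
    ).reshape(target.shape).astype(bool)

    if categorical:
        return CategoricalRaster(target, near.astype(np.int64), dict(raster.legend), mask)
    if method == "nearest":
        out = near
    else:
        vals = raster.values.copy()
        vals[raster.nodata_mask] = np.nan
        out = ndimage.map_coordinates(
            vals, coords, order=_RESAMPLE_ORDER[method], mode="nearest"
        ).reshape(target.shape)
        bad = np.isnan(out)
        out[bad] = near[bad]  # fall back to nearest where interpolation hit nodata
        mask = mask | (bad & mask)
    out = out.copy()
    out[mask] = np.nan
    return Raster(target, out, mask)


# ---------------------------------------------------------------------------
# range standardization


def range_standardize(raster: Raster) -> Raster:
    """Linearly map unmasked values onto [0, 1] (min -> 0, max -> 1).

    A constant layer carries no spatial information: it maps to all zeros
    (so it cannot contribute loss or risk) and a warning is emitted.
    """
    vals = raster.unmasked()
    if vals.size == 0:
        raise ValueError("range_standardize needs at least one unmasked cell")
    lo, hi = float(np.min(vals)), float(np.max(vals))
    out = np.full(raster.grid.shape, np.nan)
    sel = ~raster.nodata_mask
    if hi == lo:
        warnings.warn("constant layer standardized to all zeros", stacklevel=2)
        out[sel] = 0.0
    else:
        out[sel] = (raster.values[sel] - lo) / (hi - lo)
    return Raster(raster.grid, out, raster.nodata_mask.copy())


# ---------------------------------------------------------------------------
# Fisher–Jenks natural breaks


def jenks_breaks(values: Sequence[float] | np.ndarray, k: int) -> tuple[float, ...]:
    """Exact Fisher–Jenks natural breaks: k-1 strictly increasing thresholds.

    Minimizes the total within-class sum of squared deviations from class
    means over all partitions of the sorted values into ``k`` contiguous
    classes (dynamic program, O(k n^2)).  Breaks are the upper bounds (class
    maxima) of the first k-1 classes.  Ties in cost are broken toward the
    earliest feasible split, which keeps lower classes small; the result is
    deterministic.
    """
    x = np.sort(np.asarray(values, dtype=float).ravel())
    if x.size == 0 or not np.all(np.isfinite(x)):
        raise ValueError("jenks_breaks requires finite values")
    n_distinct = np.unique(x).size
    if n_distinct < k:
        raise ValueError(f"need at least k={k} distinct values, got {n_distinct}")
    if k < 2:
        raise ValueError("k must be >= 2")

    n = x.size
    # prefix sums for O(1) segment SSD:  ssd(j..i) over 0-based inclusive index
    s1 = np.concatenate([[0.0], np.cumsum(x)])
    s2 = np.concatenate([[0.0], np.cumsum(x * x)])

    def seg_cost(j: np.ndarray, i: int) -> np.ndarray:
        # cost of segment x[j..i] for vector j
        cnt = i - j + 1
        tot = s1[i + 1] - s1[j]
        sq = s2[i + 1] - s2[j]
        return sq - tot * tot / cnt

    # cost[i] = best cost of partitioning x[0..i] into the current number of classes
    idx = np.arange(n)
    cost = np.array([seg_cost(np.array([0]), i)[0] for i in range(n)])
    # back[cls][i] = start index of the last class in the optimal partition
    backs = np.zeros((k, n), dtype=np.int64)

    for cls in range(1, k):
        new_cost = np.full(n, np.inf)
        for i in range(cls, n):
            j = idx[cls : i + 1]  # start of the last class
            cand = cost[j - 1] + seg_cost(j, i)
            best = int(np.argmin(cand))  # first minimum -> earliest split
            new_cost[i] = cand[best]
            backs[cls, i] = j[best]
        cost = new_cost

    # walk back to recover class boundaries
    breaks: list[float] = []
    i = n - 1
    for cls in range(k - 1, 0, -1):
        j = int(backs[cls, i])
        breaks.append(float(x[j - 1]))  # upper bound of the class ending at j-1
        i = j - 1
    return tuple(sorted(breaks))


def jenks_breaks_raster(
    raster: Raster,
    k: int = 5,
    max_cells: int = 10_000,
    seed: int = 0,
) -> tuple[float, ...]:
    """Natural breaks of a raster's unmasked values.

    The exact dynamic program is quadratic in n, so rasters with more than
    ``max_cells`` unmasked cells are subsampled (seeded, without replacement)
    before the exact solve; the breaks are then applied to every cell.
    """
    vals = raster.unmasked()
    vals = vals[np.isfinite(vals)]
    if vals.size > max_cells:
        rng = np.random.default_rng(seed)
        vals = rng.choice(vals, size=max_cells, replace=False)
    return jenks_breaks(vals, k)


def classify(raster: Raster, breaks: Sequence[float]) -> ClassifiedMap:
    """Assign each unmasked cell a level 1..len(breaks)+1 from ``breaks``.

    Intervals are lower-open/upper-closed: a value exactly equal to a break
    belongs to the lower class.
    """
    b = tuple(float(x) for x in breaks)
    if any(b[i] >= b[i + 1] for i in range(len(b) - 1)):
        raise ValueError(f"breaks must be strictly increasing, got {b}")
    codes = np.digitize(raster.values, b, right=True) + 1
    codes[raster.nodata_mask] = 1  # placeholder under the mask
    n_levels = len(b) + 1
    labels = LEVEL_LABELS if n_levels == 5 else tuple(f"level {i}" for i in range(1, n_levels + 1))
    legend = {i + 1: labels[i] for i in range(n_levels)}
    cat = CategoricalRaster(raster.grid, codes.astype(np.int64), legend, raster.nodata_mask.copy())
    return ClassifiedMap(cat, b, tuple(labels))


# ---------------------------------------------------------------------------
# distance to polylines


def distance_raster(lines: Sequence[LineString], grid: GridSpec) -> Raster:
    """Euclidean distance (m) from each cell center to the nearest polyline.

    Cells whose footprint is intersected by a line get distance 0.  Polylines
    must be in the grid's CRS.
    """
    lines = list(lines)
    if not lines:
        raise ValueError("distance_raster requires at least one polyline")
    xs, ys = grid.cell_centers()
    points = shapely.points(xs.ravel(), ys.ravel())
    merged = MultiLineString([list(l.coords) for l in lines])
    dist = shapely.distance(points, merged).reshape(grid.shape)

    # zero out cells actually crossed by a line (center may be off the line)
    half_diag = grid.cell_size * np.sqrt(2) / 2
    cand_r, cand_c = np.nonzero((dist > 0) & (dist <= half_diag))
    for r, c in zip(cand_r, cand_c):
        x0 = grid.origin_x + c * grid.cell_size
        y1 = grid.origin_y - r * grid.cell_size
        cell = box(x0, y1 - grid.cell_size, x0 + grid.cell_size, y1)
        if merged.intersects(cell):
            dist[r, c] = 0.0
    return Raster(grid, dist)


# ---------------------------------------------------------------------------
# terrain derivatives


def horn_slope_aspect(dem: Raster) -> tuple[Raster, Raster]:
    """Slope (degrees) and aspect (degrees clockwise from north) by Horn's
    third-order finite differences on a 3x3 window.

    Aspect is in [0, 360); flat cells (zero gradient) are flagged -1.
    """
    z = dem.values
    cs = dem.grid.cell_size
    zp = np.pad(z, 1, mode="edge")

    a = zp[:-2, :-2]; b = zp[:-2, 1:-1]; c = zp[:-2, 2:]
    d = zp[1:-1, :-2];                    f = zp[1:-1, 2:]
    g = zp[2:, :-2];  h = zp[2:, 1:-1];  i = zp[2:, 2:]

    dzdx = ((c + 2 * f + i) - (a + 2 * d + g)) / (8 * cs)
    dzdy = ((g + 2 * h + i) - (a + 2 * b + c)) / (8 * cs)  # y increases downward (south)

    slope = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
    # aspect: azimuth of steepest descent, clockwise from north; rows run
    # north->south so the northward gradient component is -dzdy
    aspect = np.mod(np.degrees(np.arctan2(-dzdx, dzdy)), 360.0)
    flat = (dzdx == 0) & (dzdy == 0)
    aspect[flat] = -1.0
    return (
        Raster(dem.grid, slope, dem.nodata_mask.copy()),
        Raster(dem.grid, aspect, dem.nodata_mask.copy()),
    )


def aspect_sectors(aspect: Raster) -> CategoricalRaster:
    """Encode circular aspect into 9 sectors: 0 = flat, 1..8 = compass octants
    starting at north (N, NE, E, SE, S, SW, W, NW)."""
    codes = np.zeros(aspect.grid.shape, dtype=np.int64)
    ok = aspect.values >= 0
    codes[ok] = (np.floor(((aspect.values[ok] + 22.5) % 360.0) / 45.0)).astype(np.int64) + 1
    legend = {0: "flat", 1: "N", 2: "NE", 3: "E", 4: "SE", 5: "S", 6: "SW", 7: "W", 8: "NW"}
    return CategoricalRaster(aspect.grid, codes, legend, aspect.nodata_mask.copy())


# ---------------------------------------------------------------------------
# frequency tables


@dataclass
class FrequencyTable:
    """Per-level area, disaster count, proportion and frequency statistics.

    ``frequency`` is reported as disasters per 100 km^2 (count/area x 100):
    this is the scaling that reproduces published per-class frequency values
    even where headers nominally say per km^2.  Proportions are percent of the
    total count.  Both are rounded to 2 decimals; a level with zero area gets
    frequency NaN (never a division by zero).
    """

    levels: tuple[int, ...]
    labels: tuple[str, ...]
    area_km2: tuple[float, ...]
    count: tuple[int, ...]
    proportion_pct: tuple[float, ...]
    frequency_per_100km2: tuple[float, ...]
    n_points_total: int
    n_points_outside: int = 0

    @classmethod
    def from_area_counts(
        cls,
        area_km2: Sequence[float],
        counts: Sequence[int],
        labels: Sequence[str] | None = None,
        n_points_outside: int = 0,
    ) -> "FrequencyTable":
        """Build the table from per-level areas and disaster counts."""
        areas = [float(a) for a in area_km2]
        counts = [int(c) for c in counts]
        if len(areas) != len(counts):
            raise ValueError("areas and counts must align")
        total = sum(counts)
        if labels is None:
            labels = LEVEL_LABELS if len(areas) == 5 else [f"level {i+1}" for i in range(len(areas))]
        prop = [round(100.0 * c / total, 2) if total else 0.0 for c in counts]
        freq = [
            round(100.0 * c / a, 2) if a > 0 else float("nan")
            for c, a in zip(counts, areas)
        ]
        return cls(
            levels=tuple(range(1, len(areas) + 1)),
            labels=tuple(labels),
            area_km2=tuple(areas),
            count=tuple(counts),
            proportion_pct=tuple(prop),
            frequency_per_100km2=tuple(freq),
            n_points_total=total,
            n_points_outside=n_points_outside,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "level": self.levels,
                "label": self.labels,
                "area_km2": self.area_km2,
                "count": self.count,
                "proportion_pct": self.proportion_pct,
                "frequency_per_100km2": self.frequency_per_100km2,
            }
        )


def frequency_table(
    classified: ClassifiedMap,
    points: np.ndarray,
) -> FrequencyTable:
    """Overlay disaster points on a classified map and tabulate per level.

    ``points`` is an (n, 2) array of x, y coordinates.  Points outside the
    grid extent or on masked cells are excluded and counted in
    ``n_points_outside``.  Per level: area = unmasked cells x cell area (km^2);
    proportion = count/total x 100; frequency = count/area x 100.
    """
    cat = classified.raster
    grid = cat.grid
    pts = np.asarray(points, float).reshape(-1, 2)
    row, col = grid.point_to_cell(pts[:, 0], pts[:, 1])
    inside = grid.contains(row, col)
    row, col = row[inside], col[inside]
    on_data = ~cat.nodata_mask[row, col]
    row, col = row[on_data], col[on_data]
    n_outside = int(pts.shape[0] - row.size)

    n_levels = classified.n_levels
    levels = cat.codes[row, col]
    counts = np.bincount(levels, minlength=n_levels + 1)[1 : n_levels + 1]
    cell_counts = np.bincount(
        cat.codes[~cat.nodata_mask], minlength=n_levels + 1
    )[1 : n_levels + 1]
    areas = cell_counts * grid.cell_area_km2
    return FrequencyTable.from_area_counts(
        areas, counts, labels=classified.level_labels, n_points_outside=n_outside
    )
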