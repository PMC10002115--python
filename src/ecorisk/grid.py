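"""Core spatial data model: grid specification and raster containers.

Every layer in the pipeline — conditioning factors, hazard probabilities,
landscape indices, ecosystem services — is carried on one of the containers
defined here.  Co-registration is enforced by bit-equality of :class:`GridSpec`
fields, so a stack of layers can be combined cell-wise without resampling
surprises.

Conventions: the grid lives in a projected CRS with coordinates in meters;
row 0 is the top of the map; ``origin_x``/``origin_y`` are the coordinates of
the top-left corner of the top-left cell.  A point is assigned to the cell
``col = floor((x - origin_x)/cell_size)``, ``row = floor((origin_y - y)/cell_size)``,
so a point on a shared cell edge belongs to the cell to its right/below.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "GridSpec",
    "Raster",
    "CategoricalRaster",
    "ClassifiedMap",
    "LEVEL_LABELS",
    "GridMismatchError",
]

#: Fixed labels of every five-level classified map, from lowest to highest.
LEVEL_LABELS = ("very low", "low", "medium", "high", "very high")


class GridMismatchError(ValueError):
    """Raised when layers that must share a grid do not."""


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a raster grid in a projected CRS.

    Parameters
    ----------
    n_rows, n_cols
        Grid dimensions; both must be positive.
    cell_size
        Cell edge length in meters (square cells).
    origin_x, origin_y
        Map coordinates of the top-left corner of cell (0, 0).
    crs_tag
        Opaque identifier of the projected CRS (e.g. ``"EPSG:32650"``).
        Only compared for equality; never interpreted.
    """

    n_rows: int
    n_cols: int
    cell_size: float
    origin_x: float = 0.0
    origin_y: float = 0.0
    crs_tag: str = "LOCAL"

    def __post_init__(self) -> None:
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValueError(f"grid dimensions must be positive, got {self.n_rows}x{self.n_cols}")
        if self.cell_size <= 0:
            raise ValueError(f"cell_size must be > 0, got {self.cell_size}")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def cell_area_km2(self) -> float:
        """Area of one cell in km^2 (projected grid; no geodesic correction)."""
        return (self.cell_size / 1000.0) ** 2

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (x, y) center coordinate arrays of shape (n_rows, n_cols)."""
        cols = np.arange(self.n_cols)
        rows = np.arange(self.n_rows)
        x = self.origin_x + (cols + 0.5) * self.cell_size
        y = self.origin_y - (rows + 0.5) * self.cell_size
        return np.broadcast_to(x, self.shape).copy(), np.broadcast_to(y[:, None], self.shape).copy()

    def point_to_cell(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map point coordinates to (row, col) indices.

        Points on a cell edge go to the cell to the right/below.  Indices may
        fall outside the grid; callers decide how to treat those.
        """
        col = np.floor((np.asarray(x, float) - self.origin_x) / self.cell_size).astype(np.int64)
        row = np.floor((self.origin_y - np.asarray(y, float)) / self.cell_size).astype(np.int64)
        return row, col

    def contains(self, row: np.ndarray, col: np.ndarray) -> np.ndarray:
        return (row >= 0) & (row < self.n_rows) & (col >= 0) & (col < self.n_cols)


def _check_same_grid(a: GridSpec, b: GridSpec) -> None:
    if a != b:
        raise GridMismatchError(f"grids differ: {a} vs {b}")


@dataclass
class Raster:
    """A single-band continuous raster: values plus a nodata mask.

    Masked cells are excluded from every statistic computed downstream.
    """

    grid: GridSpec
    values: np.ndarray
    nodata_mask: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.values.shape, dtype=bool)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.values.shape != self.grid.shape:
            raise ValueError(f"values shape {self.values.shape} != grid shape {self.grid.shape}")
        if self.nodata_mask.shape != self.grid.shape:
            raise ValueError(f"mask shape {self.nodata_mask.shape} != grid shape {self.grid.shape}")

    def unmasked(self) -> np.ndarray:
        """1-D array of values at unmasked cells."""
        return self.values[~self.nodata_mask]

    def copy(self) -> "Raster":
        return Raster(self.grid, self.values.copy(), self.nodata_mask.copy())

    def with_values(self, values: np.ndarray) -> "Raster":
        """Same grid and mask, new values."""
        return Raster(self.grid, np.asarray(values, float), self.nodata_mask.copy())


@dataclass
class CategoricalRaster:
    """A single-band categorical raster with a code -> label legend."""

    grid: GridSpec
    codes: np.ndarray
    legend: Mapping[int, str]
    nodata_mask: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes)
        if not np.issubdtype(self.codes.dtype, np.integer):
            raise ValueError("categorical codes must be integers")
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.codes.shape, dtype=bool)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.codes.shape != self.grid.shape:
            raise ValueError(f"codes shape {self.codes.shape} != grid shape {self.grid.shape}")
        self.legend = dict(self.legend)
        present = np.unique(self.codes[~self.nodata_mask])
        missing = [int(c) for c in present if int(c) not in self.legend]
        if missing:
            raise ValueError(f"codes {missing} missing from legend {sorted(self.legend)}")

    def unmasked(self) -> np.ndarray:
        return self.codes[~self.nodata_mask]

    def copy(self) -> "CategoricalRaster":
        return CategoricalRaster(self.grid, self.codes.copy(), dict(self.legend), self.nodata_mask.copy())


@dataclass
class ClassifiedMap:
    """A five-level map (codes 1..5) plus the breaks that produced it.

    Intervals are lower-open / upper-closed: a value exactly equal to a break
    belongs to the lower class.
    """

    raster: CategoricalRaster
    breaks: tuple[float, ...]
    level_labels: tuple[str, ...] = field(default=LEVEL_LABELS)

    def __post_init__(self) -> None:
        b = tuple(float(x) for x in self.breaks)
        if any(b[i] >= b[i + 1] for i in range(len(b) - 1)):
            raise ValueError(f"breaks must be strictly increasing, got {b}")
        self.breaks = b

    @property
    def n_levels(self) -> int:
        return len(self.breaks) + 1


def stack_grids(*layers: Raster | CategoricalRaster) -> GridSpec:
    """Return the shared GridSpec of co-registered layers, or raise."""
    if not layers:
        raise ValueError("no layers given")
    g = layers[0].grid
    for layer in layers[1:]:
        _check_same_grid(g, layer.grid)
    return g


def union_nodata(*layers: Raster | CategoricalRaster) -> np.ndarray:
    """Union of the nodata masks of co-registered layers."""
    stack_grids(*layers)
    mask = np.zeros(layers[0].grid.shape, dtype=bool)
    for layer in layers:
        mask |= layer.nodata_mask
    return mask
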