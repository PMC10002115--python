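"""Landscape-pattern vulnerability on a coarse analysis grid.

The region is tiled into square analysis cells (default 0.5 km).  Within each
cell the land-cover mosaic yields patch density (PD), the landscape division
index (DIVISION), and a landscape disturbance index (LDI) combining
fragmentation C_i, separation S_i and dominance D with weights
(a, b, c) = (0.5, 0.3, 0.2).  The three components are range-standardized
across all cells and averaged into the composite vulnerability index
VI = (LDI + PD + DIVISION) / 3, classified into five levels by natural breaks.

Formulas per class i within one analysis cell of landscape area A (km^2):
  C_i = N_i / A_i                      (patches per km^2 of the class)
  S_i = (A / (2 A_i)) * sqrt(N_i / A)  (separation)
  D   = ln(m) + sum_i (A_i/A) ln(A_i/A)   (dominance; 0 when m = 1)
  DIVISION = 1 - sum_patches (a_p / A)^2
Class-level C_i and S_i are aggregated to the cell by area weights A_i/A
before entering LDI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .geodata import classify, jenks_breaks_raster, range_standardize
from .grid import CategoricalRaster, ClassifiedMap, GridSpec, Raster

__all__ = [
    "LandscapeCellMetrics",
    "AnalysisGrid",
    "label_patches",
    "cell_metrics",
    "vulnerability_map",
    "DEFAULT_LDI_WEIGHTS",
]

DEFAULT_LDI_WEIGHTS = (0.5, 0.3, 0.2)  # (a, b, c) on (C, S, D)

_STRUCTURE = {
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], bool),
    8: np.ones((3, 3), bool),
}


@dataclass
class LandscapeCellMetrics:
    """All landscape indices of one analysis cell."""

    area_km2: float  # A: landscape area of the cell
    n_classes: int  # m
    class_area_km2: dict[int, float]  # A_i
    class_patches: dict[int, int]  # N_i
    pd: float  # patches per km^2
    division: float  # in [0, 1)
    fragmentation: float  # area-weighted C
    separation: float  # area-weighted S
    dominance: float  # D
    ldi: float


@dataclass
class AnalysisGrid:
    """Tiling of a fine land-cover grid into coarse analysis cells.

    Fine cells are assigned to the analysis cell containing their center, so
    cell blocks may differ by one fine cell when the ratio of resolutions is
    not an integer; edge cells keep their true (smaller) area.
    """

    source: GridSpec
    cell_size: float = 500.0
    row_bounds: np.ndarray = field(init=False)
    col_bounds: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.cell_size < self.source.cell_size:
            raise ValueError("analysis cell must be coarser than the land-cover grid")
        self.row_bounds = self._bounds(self.source.n_rows)
        self.col_bounds = self._bounds(self.source.n_cols)

    def _bounds(self, n: int) -> np.ndarray:
        block = np.floor((np.arange(n) + 0.5) * self.source.cell_size / self.cell_size)
        starts = np.nonzero(np.diff(block, prepend=-1))[0]
        return np.append(starts, n)

    @property
    def n_rows(self) -> int:
        return len(self.row_bounds) - 1

    @property
    def n_cols(self) -> int:
        return len(self.col_bounds) - 1

    def grid_spec(self) -> GridSpec:
        return GridSpec(
            self.n_rows,
            self.n_cols,
            self.cell_size,
            self.source.origin_x,
            self.source.origin_y,
            self.source.crs_tag,
        )

    def block(self, i: int, j: int) -> tuple[slice, slice]:
        return (
            slice(self.row_bounds[i], self.row_bounds[i + 1]),
            slice(self.col_bounds[j], self.col_bounds[j + 1]),
        )


def label_patches(
    landcover: CategoricalRaster, connectivity: int = 8
) -> tuple[np.ndarray, pd.DataFrame]:
    """Label maximal connected same-class components.

    Returns (label raster, per-patch table with columns patch_id/class_code/
    cells).  Labels start at 1 in row-major discovery order; masked cells get
    label 0.
    """
    if connectivity not in _STRUCTURE:
        raise ValueError("connectivity must be 4 or 8")
    codes = landcover.codes
    if codes.size == 0:
        raise ValueError("empty raster")
    valid = ~landcover.nodata_mask
    labels = np.zeros(codes.shape, dtype=np.int64)
    next_label = 1
    records = []
    for code in np.unique(codes[valid]):
        comp, n_comp = ndimage.label((codes == code) & valid, structure=_STRUCTURE[connectivity])
        for k in range(1, n_comp + 1):
            sel = comp == k
            labels[sel] = 0  # placeholder; relabeled below for discovery order
            records.append((code, sel))
    # deterministic relabeling: order patches by their first row-major cell
    order = sorted(
        range(len(records)),
        key=lambda i: int(np.flatnonzero(records[i][1].ravel())[0]),
    )
    rows = []
    for new_id, i in enumerate(order, start=1):
        code, sel = records[i]
        labels[sel] = new_id
        rows.append({"patch_id": new_id, "class_code": int(code), "cells": int(sel.sum())})
    return labels, pd.DataFrame(rows)


def cell_metrics(
    landcover: CategoricalRaster,
    weights: tuple[float, float, float] = DEFAULT_LDI_WEIGHTS,
    connectivity: int = 8,
) -> LandscapeCellMetrics:
    """Landscape metrics of a single analysis cell's land-cover sub-raster."""
    valid = ~landcover.nodata_mask
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise ValueError("cell is fully masked")
    cell_area = landcover.grid.cell_area_km2
    A = n_valid * cell_area

    labels, patches = label_patches(landcover, connectivity)
    n_patches = len(patches)
    pd_index = n_patches / A
    division = 1.0 - float(np.sum((patches["cells"].to_numpy() * cell_area / A) ** 2))

    class_area: dict[int, float] = {}
    class_patches: dict[int, int] = {}
    for code, grp in patches.groupby("class_code"):
        class_area[int(code)] = float(grp["cells"].sum()) * cell_area
        class_patches[int(code)] = len(grp)
    m = len(class_area)

    dominance = 0.0
    frag = 0.0
    sep = 0.0
    for code, a_i in class_area.items():
        share = a_i / A
        dominance += share * np.log(share)
        n_i = class_patches[code]
        c_i = n_i / a_i
        s_i = (A / (2.0 * a_i)) * np.sqrt(n_i / A)
        frag += share * c_i
        sep += share * s_i
    dominance += np.log(m)

    a, b, c = weights
    ldi = a * frag + b * sep + c * dominance
    return LandscapeCellMetrics(
        area_km2=A,
        n_classes=m,
        class_area_km2=class_area,
        class_patches=class_patches,
        pd=pd_index,
        division=division,
        fragmentation=frag,
        separation=sep,
        dominance=float(dominance),
        ldi=float(ldi),
    )


def vulnerability_map(
    landcover: CategoricalRaster,
    cell_size: float = 500.0,
    weights: tuple[float, float, float] = DEFAULT_LDI_WEIGHTS,
    connectivity: int = 8,
    jenks_seed: int = 0,
) -> tuple[Raster, ClassifiedMap, pd.DataFrame]:
    """Composite vulnerability index per analysis cell.

    Computes LDI, PD and DIVISION per cell, range-standardizes each across all
    cells, and averages them into VI in [0, 1]; VI is then classified into
    five levels by natural breaks.  Returns (VI raster on the analysis grid,
    classified map, per-cell metrics table).

    An advisory check warns (never fails) when the analysis cell is less than
    2x or more than 5x the average patch size.
    """
    ag = AnalysisGrid(landcover.grid, cell_size)
    if ag.n_rows * ag.n_cols < 2:
        raise ValueError(
            "a single analysis cell cannot be standardized; use a larger region "
            "or a smaller cell size"
        )
    gspec = ag.grid_spec()
    ldi = np.full(gspec.shape, np.nan)
    pdens = np.full(gspec.shape, np.nan)
    divi = np.full(gspec.shape, np.nan)
    rows = []
    for i in range(ag.n_rows):
        for j in range(ag.n_cols):
            rs, cs = ag.block(i, j)
            sub = CategoricalRaster(
                GridSpec(
                    rs.stop - rs.start,
                    cs.stop - cs.start,
                    landcover.grid.cell_size,
                    crs_tag=landcover.grid.crs_tag,
                ),
                landcover.codes[rs, cs],
                dict(landcover.legend),
                landcover.nodata_mask[rs, cs],
            )
            if (~sub.nodata_mask).sum() == 0:
                rows.append({"row": i, "col": j, "valid": False})
                continue
            met = cell_metrics(sub, weights, connectivity)
            ldi[i, j] = met.ldi
            pdens[i, j] = met.pd
            divi[i, j] = met.division
            rows.append(
                {
                    "row": i,
                    "col": j,
                    "valid": True,
                    "area_km2": met.area_km2,
                    "n_classes": met.n_classes,
                    "pd": met.pd,
                    "division": met.division,
                    "fragmentation": met.fragmentation,
                    "separation": met.separation,
                    "dominance": met.dominance,
                    "ldi": met.ldi,
                }
            )
    metrics = pd.DataFrame(rows)

    # advisory scale check: analysis cell vs mean patch size over the region
    _, all_patches = label_patches(landcover, connectivity)
    mean_patch = all_patches["cells"].mean() * landcover.grid.cell_area_km2
    ratio = gspec.cell_area_km2 / mean_patch if mean_patch > 0 else np.inf
    if not 2.0 <= ratio <= 5.0:
        warnings.warn(
            f"analysis cell is {ratio:.1f}x the average patch size "
            "(2-5x recommended)",
            stacklevel=2,
        )

    nanmask = np.isnan(ldi)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant-component warnings are expected on toy maps
        vi_components = [
            range_standardize(Raster(gspec, np.nan_to_num(x, nan=0.0), nanmask))
            for x in (ldi, pdens, divi)
        ]
    vi_vals = sum(c.values for c in vi_components) / 3.0
    vi = Raster(gspec, vi_vals, nanmask)

    if np.unique(vi.unmasked()).size >= 5:
        classified = classify(vi, jenks_breaks_raster(vi, k=5, seed=jenks_seed))
    else:
        # degenerate landscape (e.g. uniform cover): no five-level map exists
        classified = None
        warnings.warn("fewer than 5 distinct VI values; classification skipped", stacklevel=2)
    return vi, classified, metrics
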