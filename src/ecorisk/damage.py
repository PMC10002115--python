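"""Potential damage: ecosystem-service losses plus population exposure.

Three ecosystem services stand for what a disaster would destroy:

* water conservation by the water balance, Qwr = (P - R - ET) x 1e-3 x area,
  in m^3/a per cell (negative budgets clamp to zero — a conservation service
  cannot be negative);
* soil conservation by RUSLE as the gap between potential and actual erosion,
  SOR = R K LS - R K LS C P = R K LS (1 - C P), in t hm^-2 a^-1;
* net primary productivity directly (lush vegetation means more to lose).

The three service layers are range-standardized and summed into the
ecological-loss layer; that layer, again standardized, is added to the
standardized population-exposure layer and the sum rescaled to [0, 1] as the
total potential damage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .geodata import classify, jenks_breaks_raster, range_standardize
from .grid import CategoricalRaster, ClassifiedMap, Raster, stack_grids, union_nodata

__all__ = [
    "DamageLayers",
    "water_conservation",
    "runoff_from_landcover",
    "ls_factor",
    "c_factor",
    "p_factor",
    "rusle",
    "potential_damage",
    "DEFAULT_RUNOFF_COEFFICIENTS",
    "DEFAULT_P_FACTORS",
]

#: Runoff coefficients by land-cover class (fraction of precipitation that
#: leaves as surface runoff).  Values are conventional hydrology-handbook
#: magnitudes: dense forest intercepts most rainfall, sealed surfaces shed it.
DEFAULT_RUNOFF_COEFFICIENTS: Mapping[int, float] = {
    1: 0.10,  # forest
    2: 0.15,  # shrubland
    3: 0.20,  # grassland
    4: 0.30,  # cropland
    5: 1.00,  # water
    6: 0.70,  # build-up
    7: 0.50,  # bareland
}

#: RUSLE support-practice (management) factor by land-cover class.
DEFAULT_P_FACTORS: Mapping[int, float] = {
    1: 1.0,  # forest
    2: 1.0,  # shrubland
    3: 1.0,  # grassland
    4: 0.35,  # cropland (contour practices assumed)
    5: 0.0,  # water
    6: 0.0,  # build-up
    7: 1.0,  # bareland
}


@dataclass
class DamageLayers:
    """All potential-damage surfaces and their five-level classifications."""

    qwr: Raster  # water conservation, m^3/a per cell
    sor: Raster  # soil conservation, t hm^-2 a^-1
    npp: Raster  # g C m^-2 a^-1
    eco_loss: Raster  # sum of three standardized services, [0, 3]
    population: Raster  # persons per cell
    total_damage: Raster  # [0, 1]
    eco_loss_classified: ClassifiedMap | None = None
    population_classified: ClassifiedMap | None = None
    total_classified: ClassifiedMap | None = None


def _require_nonnegative(raster: Raster, name: str) -> None:
    vals = raster.unmasked()
    if vals.size and np.nanmin(vals) < 0:
        raise ValueError(f"layer {name!r} has negative values (min {np.nanmin(vals):g})")


def water_conservation(precip: Raster, runoff: Raster, et: Raster) -> Raster:
    """Water conservation volume per cell (m^3/a) from the water balance.

    Depth (P - R - ET) in mm/a converts to meters via 1e-3 and multiplies the
    cell area; negative budgets clamp to zero.
    """
    grid = stack_grids(precip, runoff, et)
    for r, n in ((precip, "precipitation"), (runoff, "runoff"), (et, "evapotranspiration")):
        _require_nonnegative(r, n)
    depth_m = (precip.values - runoff.values - et.values) * 1e-3
    volume = np.clip(depth_m, 0.0, None) * grid.cell_size**2
    return Raster(grid, volume, union_nodata(precip, runoff, et))


def runoff_from_landcover(
    precip: Raster,
    landcover: CategoricalRaster,
    coefficients: Mapping[int, float] = DEFAULT_RUNOFF_COEFFICIENTS,
) -> Raster:
    """Surface runoff R = coefficient(class) x P per cell (mm/a)."""
    stack_grids(precip, landcover)
    present = np.unique(landcover.unmasked())
    missing = [int(c) for c in present if int(c) not in coefficients]
    if missing:
        raise ValueError(f"no runoff coefficient for land-cover classes {missing}")
    bad = {c: v for c, v in coefficients.items() if not 0.0 <= v <= 1.0}
    if bad:
        raise ValueError(f"runoff coefficients must lie in [0, 1]: {bad}")
    lut = np.zeros(int(max(coefficients)) + 1)
    for c, v in coefficients.items():
        lut[c] = v
    runoff = lut[np.clip(landcover.codes, 0, len(lut) - 1)] * precip.values
    return Raster(precip.grid, runoff, union_nodata(precip, landcover))


# ---------------------------------------------------------------------------
# RUSLE factors

_D8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def ls_factor(dem: Raster, slope_length_cap: float = 120.0) -> Raster:
    """RUSLE topographic factor LS from a DEM.

    Slope length accumulates along steepest-descent flow paths (capped at
    ``slope_length_cap`` meters, starting from one cell size at divides);
    L = (lambda / 22.13)^m with the exponent m piecewise in slope, and S from
    the McCool piecewise slope equations.  Flat terrain yields the uniform
    minimum (lambda at its initial value, S at its zero-slope value).
    """
    g = dem.grid
    if g.cell_size < 1.0:
        raise ValueError(
            "cell size below 1 m suggests a geographic (degree) grid; "
            "LS requires a projected DEM in meters"
        )
    z = dem.values
    n_rows, n_cols = g.shape

    # steepest-descent receiver of every cell (-1 where no downslope neighbor)
    best_drop = np.full((n_rows, n_cols), 0.0)
    recv_k = np.full((n_rows, n_cols), -1, dtype=np.int64)
    for k, (dr, dc) in enumerate(_D8):
        rr = np.clip(np.arange(n_rows)[:, None] + dr, 0, n_rows - 1)
        cc = np.clip(np.arange(n_cols)[None, :] + dc, 0, n_cols - 1)
        d = g.cell_size * np.hypot(dr, dc)
        drop = (z - z[rr, cc]) / d
        better = drop > best_drop
        best_drop = np.where(better, drop, best_drop)
        recv_k = np.where(better, k, recv_k)

    # accumulate slope length from divides downslope (process by descending z)
    lam = np.full((n_rows, n_cols), float(g.cell_size))
    order = np.argsort(z.ravel())[::-1]
    rows, cols = np.unravel_index(order, z.shape)
    for r, c in zip(rows, cols):
        k = recv_k[r, c]
        if k < 0:
            continue
        dr, dc = _D8[k]
        rr, cc = r + dr, c + dc
        if not (0 <= rr < n_rows and 0 <= cc < n_cols):
            continue
        d = g.cell_size * np.hypot(dr, dc)
        lam[rr, cc] = max(lam[rr, cc], min(lam[r, c] + d, slope_length_cap))

    # slope (radians and percent) from Horn gradients
    from .geodata import horn_slope_aspect

    slope_deg, _ = horn_slope_aspect(dem)
    theta = np.radians(slope_deg.values)
    slope_pct = np.tan(theta) * 100.0

    m = np.where(slope_pct >= 5.0, 0.5, np.where(slope_pct >= 3.0, 0.4,
        np.where(slope_pct >= 1.0, 0.3, 0.2)))
    L = (lam / 22.13) ** m
    S = np.where(slope_pct < 9.0, 10.8 * np.sin(theta) + 0.03, 16.8 * np.sin(theta) - 0.5)
    ls = L * S
    return Raster(g, ls, dem.nodata_mask.copy())


def c_factor(ndvi: Raster, alpha: float = 2.0, beta: float = 1.0) -> Raster:
    """RUSLE vegetation-cover factor from NDVI.

    C = exp(-alpha * NDVI / (beta - NDVI)) clamped to [0, 1]; non-positive
    NDVI (bare or non-vegetated) maps to C = 1.
    """
    vals = ndvi.unmasked()
    if vals.size and (np.nanmin(vals) < -1.0 or np.nanmax(vals) > 1.0):
        raise ValueError("NDVI must lie in [-1, 1]")
    if vals.size and beta <= np.nanmax(vals):
        raise ValueError(f"beta={beta} must exceed the maximum NDVI ({np.nanmax(vals):g})")
    v = ndvi.values
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.exp(-alpha * v / (beta - v))
    c = np.where(v <= 0.0, 1.0, c)
    return Raster(ndvi.grid, np.clip(c, 0.0, 1.0), ndvi.nodata_mask.copy())


def p_factor(
    landcover: CategoricalRaster,
    table: Mapping[int, float] = DEFAULT_P_FACTORS,
) -> Raster:
    """RUSLE support-practice factor by land-use lookup."""
    present = np.unique(landcover.unmasked())
    missing = [int(c) for c in present if int(c) not in table]
    if missing:
        raise ValueError(f"no P factor for land-cover classes {missing}")
    bad = {c: v for c, v in table.items() if not 0.0 <= v <= 1.0}
    if bad:
        raise ValueError(f"P factors must lie in [0, 1]: {bad}")
    lut = np.zeros(int(max(table)) + 1)
    for c, v in table.items():
        lut[c] = v
    return Raster(
        landcover.grid,
        lut[np.clip(landcover.codes, 0, len(lut) - 1)],
        landcover.nodata_mask.copy(),
    )


def rusle(
    erosivity: Raster, erodibility: Raster, ls: Raster, c: Raster, p: Raster
) -> tuple[Raster, Raster, Raster]:
    """Potential erosion, actual erosion, and soil conservation.

    SEp = R K LS; SEr = R K LS C P; SOR = SEp - SEr = SEp (1 - C P), all in
    t hm^-2 a^-1.  Raises if C x P exceeds 1 anywhere (SOR would go negative).
    """
    grid = stack_grids(erosivity, erodibility, ls, c, p)
    for r, n in ((erosivity, "R"), (erodibility, "K"), (ls, "LS")):
        _require_nonnegative(r, n)
    cp = c.values * p.values
    mask = union_nodata(erosivity, erodibility, ls, c, p)
    if np.nanmax(np.where(mask, 0.0, cp)) > 1.0 + 1e-12:
        raise ValueError("C x P exceeds 1 somewhere; soil conservation would be negative")
    sep = erosivity.values * erodibility.values * ls.values
    ser = sep * cp
    sor = sep - ser
    return (
        Raster(grid, sep, mask.copy()),
        Raster(grid, ser, mask.copy()),
        Raster(grid, sor, mask.copy()),
    )


def potential_damage(
    qwr: Raster,
    sor: Raster,
    npp: Raster,
    population: Raster,
    classify_levels: bool = True,
    jenks_seed: int = 0,
) -> DamageLayers:
    """Combine the three services and population exposure into total damage.

    eco_loss = std(Qwr) + std(SOR) + std(NPP); total = std(eco_loss) +
    std(population), rescaled to [0, 1].  Constant layers contribute zero (with
    a warning).  Five-level classified maps of ecological loss, population and
    total damage are attached when ``classify_levels`` is true.
    """
    stack_grids(qwr, sor, npp, population)
    mask = union_nodata(qwr, sor, npp, population)

    def std(r: Raster) -> Raster:
        return range_standardize(Raster(r.grid, r.values, mask))

    eco = std(qwr).values + std(sor).values + std(npp).values
    eco_loss = Raster(qwr.grid, eco, mask.copy())
    total = std(eco_loss).values + std(population).values
    total_damage = range_standardize(Raster(qwr.grid, total, mask.copy()))

    layers = DamageLayers(
        qwr=qwr, sor=sor, npp=npp,
        eco_loss=eco_loss,
        population=population,
        total_damage=total_damage,
    )
    if classify_levels:
        for attr, source in (
            ("eco_loss_classified", eco_loss),
            ("population_classified", Raster(population.grid, population.values, mask)),
            ("total_classified", total_damage),
        ):
            vals = source.unmasked()
            if np.unique(vals).size >= 5:
                breaks = jenks_breaks_raster(source, k=5, seed=jenks_seed)
                setattr(layers, attr, classify(source, breaks))
            else:
                warnings.warn(f"{attr}: fewer than 5 distinct values; skipped", stacklevel=2)
    return layers
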