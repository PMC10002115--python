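"""Synthetic mountainous study region with a planted disaster process.

Real assessments of this kind run on a stack of co-registered layers — DEM and
its derivatives, precipitation, NDVI, land cover, lithology, distances to
faults and rivers, population, NPP, evapotranspiration, rainfall erosivity and
soil erodibility — none of which can be shipped with a package.  This module
generates all of them for a fictitious mountain region, plus a disaster point
inventory drawn from a *known* logistic dependence on a chosen subset of
factors.  Because the generating weights are recorded, the hazard model's
ability to recover them (factor importance ranking, held-out AUC) is testable.

Everything is a pure function of (config, seed): two calls with the same
configuration produce bit-identical layers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage
from shapely.geometry import LineString

from .geodata import distance_raster, horn_slope_aspect, aspect_sectors
from .grid import CategoricalRaster, GridSpec, Raster

__all__ = [
    "RegionConfig",
    "PlantedHazardModel",
    "ConditioningStack",
    "SyntheticRegion",
    "generate_terrain",
    "derive_hydrofeatures",
    "generate_covariates",
    "plant_disasters",
    "generate_region",
    "LANDCOVER_LEGEND",
    "LITHOLOGY_LEGEND",
]

#: The seven land-cover classes used throughout (codes 1..7).
LANDCOVER_LEGEND = {
    1: "forest",
    2: "shrubland",
    3: "grassland",
    4: "cropland",
    5: "water",
    6: "build-up",
    7: "bareland",
}

#: Five lithological groups, ordered roughly hard -> loose.
LITHOLOGY_LEGEND = {
    1: "dolomite / thick stratified rhyolite",
    2: "quartz sandstone / silastic conglomerate",
    3: "pyroclastic / metamorphic rocks",
    4: "mudslate / coal seam",
    5: "clay / loose sediments",
}

#: Canonical order of the nine hazard conditioning factors.
FACTOR_NAMES = (
    "elevation",
    "slope",
    "precipitation",
    "ndvi",
    "aspect",
    "landuse",
    "lithology",
    "dist_fault",
    "dist_river",
)

#: Factors carried as categorical codes (the rest are continuous).
CATEGORICAL_FACTORS = ("aspect", "landuse", "lithology")


@dataclass(frozen=True)
class RegionConfig:
    """Recipe for one synthetic region.

    Defaults describe a 256x256-cell block of subtropical mountain terrain at
    30 m resolution (~7.7 km on a side): ~1.2 km of relief, annual rainfall
    rising with elevation from ~1400 mm/a, three rivers, two faults.
    """

    grid: GridSpec = field(
        default_factory=lambda: GridSpec(256, 256, 30.0, 500_000.0, 3_000_000.0, "EPSG:32650")
    )
    seed: int = 0
    relief_amplitude: float = 1200.0  # m
    spectral_exponent: float = 1.8  # power-spectrum rolloff; higher = smoother
    precip_base: float = 1400.0  # mm/a at elevation 0
    # a moderate orographic gradient plus strong mesoscale variability keeps
    # precipitation from collapsing onto elevation, so each factor carries
    # identifiable signal of its own
    precip_lapse: float = 0.15  # mm/a per m of elevation
    precip_noise_sd: float = 150.0  # mm/a, spatially correlated
    n_faults: int = 2
    n_rivers: int = 3
    population_scale: float = 50.0  # persons per built-up cell, order of magnitude
    #: optional ordered (code, predicate) rules replacing the built-in cascade;
    #: each predicate maps (elev01, slope_deg, ndvi, noise) arrays -> bool array.
    #: The rules must cover every cell or generation fails.
    landcover_rules: tuple = None  # type: ignore[assignment]


@dataclass(frozen=True)
class PlantedHazardModel:
    """Ground-truth logistic disaster process.

    Cell probability = sigmoid(intercept + sum_i w_i * z_i) where z_i are the
    range-standardized continuous factors named in ``factor_weights``.  The
    default plants disasters on steep, wet, sparsely vegetated low ground —
    the qualitative pattern reported for real mountain provinces — and leaves
    the remaining factors as zero-weight decoys.
    """

    factor_weights: Mapping[str, float] = field(
        default_factory=lambda: {
            "slope": 10.0,
            "precipitation": 6.0,
            "ndvi": -8.0,
            "elevation": -5.0,
        }
    )
    intercept: float = -3.0
    n_events: int = 800

    def __post_init__(self) -> None:
        unknown = set(self.factor_weights) - set(FACTOR_NAMES)
        if unknown:
            raise ValueError(f"weights reference unknown factors: {sorted(unknown)}")


@dataclass
class ConditioningStack:
    """The nine co-registered hazard conditioning factors."""

    elevation: Raster
    slope: Raster
    precipitation: Raster
    ndvi: Raster
    aspect: CategoricalRaster
    landuse: CategoricalRaster
    lithology: CategoricalRaster
    dist_fault: Raster
    dist_river: Raster

    factor_names = FACTOR_NAMES

    def __post_init__(self) -> None:
        g = self.elevation.grid
        for name in FACTOR_NAMES:
            if self.layer(name).grid != g:
                raise ValueError(f"factor {name!r} is not co-registered with elevation")

    @property
    def grid(self) -> GridSpec:
        return self.elevation.grid

    def layer(self, name: str) -> Raster | CategoricalRaster:
        return getattr(self, name)

    def nodata_mask(self) -> np.ndarray:
        mask = np.zeros(self.grid.shape, dtype=bool)
        for name in FACTOR_NAMES:
            mask |= self.layer(name).nodata_mask
        return mask

    def feature_matrix(self) -> tuple[np.ndarray, np.ndarray]:
        """(n_valid x 9 feature matrix, flat indices of valid cells)."""
        mask = self.nodata_mask()
        idx = np.nonzero(~mask.ravel())[0]
        cols = []
        for name in FACTOR_NAMES:
            layer = self.layer(name)
            arr = layer.codes if isinstance(layer, CategoricalRaster) else layer.values
            cols.append(np.asarray(arr, float).ravel()[idx])
        return np.column_stack(cols), idx


@dataclass
class SyntheticRegion:
    """Everything one synthetic region provides."""

    config: RegionConfig
    stack: ConditioningStack
    rivers: list[LineString]
    faults: list[LineString]
    river_mask: CategoricalRaster
    population: Raster
    npp: Raster
    evapotranspiration: Raster
    rainfall_erosivity: Raster
    soil_erodibility: Raster
    events_xy: np.ndarray  # (n, 2) planted disaster coordinates
    planted_model: PlantedHazardModel
    true_probability: Raster  # the planted per-cell logistic probability


# ---------------------------------------------------------------------------
# terrain


def generate_terrain(config: RegionConfig) -> Raster:
    """Fractal elevation surface by spectral synthesis.

    White Gaussian noise is shaped in the Fourier domain with an isotropic
    power-law filter |f|^(-spectral_exponent) and the result rescaled to
    [0, relief_amplitude].  Deterministic in (grid, seed).
    """
    g = config.grid
    if g.n_rows < 64 or g.n_cols < 64:
        raise ValueError(f"terrain grid must be at least 64x64, got {g.n_rows}x{g.n_cols}")
    rng = np.random.default_rng(config.seed)
    noise = rng.standard_normal(g.shape)
    fy = np.fft.fftfreq(g.n_rows)[:, None]
    fx = np.fft.fftfreq(g.n_cols)[None, :]
    freq = np.hypot(fy, fx)
    freq[0, 0] = 1.0  # keep the DC term finite; it only shifts the mean
    spectrum = np.fft.fft2(noise) * freq ** (-config.spectral_exponent)
    z = np.real(np.fft.ifft2(spectrum))
    lo, hi = z.min(), z.max()
    if config.relief_amplitude == 0 or hi == lo:
        return Raster(g, np.zeros(g.shape))
    z = (z - lo) / (hi - lo) * config.relief_amplitude
    return Raster(g, z)


# ---------------------------------------------------------------------------
# hydrography and faults

_D8_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _trace_descent(z: np.ndarray, r: int, c: int, max_steps: int) -> list[tuple[int, int]]:
    """Follow steepest 8-neighbor descent from (r, c) until a pit or the edge.

    Ties go to the lowest flat index (row-major order of the offsets above).
    """
    n_rows, n_cols = z.shape
    path = [(r, c)]
    for _ in range(max_steps):
        best = None
        best_grad = 0.0
        for dr, dc in _D8_OFFSETS:
            rr, cc = r + dr, c + dc
            if not (0 <= rr < n_rows and 0 <= cc < n_cols):
                continue
            grad = (z[r, c] - z[rr, cc]) / np.hypot(dr, dc)
            if grad > best_grad:
                best_grad = grad
                best = (rr, cc)
        if best is None:
            break
        r, c = best
        path.append((r, c))
        if r in (0, n_rows - 1) or c in (0, n_cols - 1):
            break
    return path


def derive_hydrofeatures(
    elevation: Raster, config: RegionConfig
) -> tuple[list[LineString], CategoricalRaster, list[LineString]]:
    """Rivers, a river-cell mask, and fault lines for the region.

    Rivers start at seeded high-elevation cells (proxies for high-accumulation
    headwaters) and follow steepest descent; faults are random straight
    segments spanning the region.  Returns (rivers, river_mask, faults).
    """
    g = elevation.grid
    z = elevation.values
    if np.ptp(z) == 0:
        raise ValueError(
            "flat terrain has no drainage; use relief_amplitude > 0 to derive rivers"
        )
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))

    # headwaters: sample among the highest-elevation interior cells
    interior = z[2:-2, 2:-2]
    thresh = np.quantile(interior, 0.9)
    cand = np.argwhere(z >= thresh)
    cand = cand[(cand[:, 0] > 1) & (cand[:, 0] < g.n_rows - 2)
                & (cand[:, 1] > 1) & (cand[:, 1] < g.n_cols - 2)]
    if len(cand) < config.n_rivers:
        cand = np.argwhere(z >= np.quantile(z, 0.5))
    starts = cand[rng.choice(len(cand), size=config.n_rivers, replace=False)]

    rivers: list[LineString] = []
    mask = np.zeros(g.shape, dtype=bool)
    max_steps = 4 * (g.n_rows + g.n_cols)
    for r0, c0 in starts:
        path = _trace_descent(z, int(r0), int(c0), max_steps)
        if len(path) < 2:  # pit right at the source; nudge to its lowest neighbor
            r, c = int(r0), int(c0)
            path = [(r, c), (min(r + 1, g.n_rows - 1), c)]
        coords = [
            (g.origin_x + (c + 0.5) * g.cell_size, g.origin_y - (r + 0.5) * g.cell_size)
            for r, c in path
        ]
        rivers.append(LineString(coords))
        for r, c in path:
            mask[r, c] = True

    codes = mask.astype(np.int64)
    river_mask = CategoricalRaster(g, codes, {0: "land", 1: "river"})

    # faults: straight chords across the extent
    faults: list[LineString] = []
    w = g.n_cols * g.cell_size
    h = g.n_rows * g.cell_size
    for _ in range(config.n_faults):
        cx = g.origin_x + rng.uniform(0.2, 0.8) * w
        cy = g.origin_y - rng.uniform(0.2, 0.8) * h
        theta = rng.uniform(0, np.pi)
        dx, dy = np.cos(theta), np.sin(theta)
        span = np.hypot(w, h)
        faults.append(
            LineString([(cx - dx * span, cy - dy * span), (cx + dx * span, cy + dy * span)])
        )
    return rivers, river_mask, faults


# ---------------------------------------------------------------------------
# covariates


def _correlated_noise(rng: np.random.Generator, shape: tuple[int, int], sigma: float) -> np.ndarray:
    """Unit-variance spatially correlated Gaussian field (smoothed white noise)."""
    field = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    sd = field.std()
    return field / sd if sd > 0 else field


def _classify_landcover(
    elev01: np.ndarray,
    slope: np.ndarray,
    ndvi: np.ndarray,
    river: np.ndarray,
    noise: np.ndarray,
) -> np.ndarray:
    """Rule cascade over (elevation, slope, NDVI, noise) -> the 7 classes.

    The final rule is a catch-all, so the rule set covers the whole domain by
    construction.
    """
    codes = np.zeros(elev01.shape, dtype=np.int64)
    codes[river] = 5  # water
    free = ~river
    builtup = free & (elev01 < 0.25) & (slope < 8) & (noise > 0.8)
    codes[builtup] = 6
    free &= ~builtup
    cropland = free & (elev01 < 0.45) & (slope < 12) & (ndvi > 0.25)
    codes[cropland] = 4
    free &= ~cropland
    bareland = free & ((ndvi < 0.12) | ((elev01 > 0.85) & (slope > 30)))
    codes[bareland] = 7
    free &= ~bareland
    grassland = free & (ndvi < 0.4)
    codes[grassland] = 3
    free &= ~grassland
    shrub = free & (ndvi < 0.6)
    codes[shrub] = 2
    free &= ~shrub
    codes[free] = 1  # forest: the wet, well-vegetated remainder
    return codes


def generate_covariates(
    elevation: Raster,
    rivers: Sequence[LineString],
    river_mask: CategoricalRaster,
    faults: Sequence[LineString],
    config: RegionConfig,
) -> tuple[ConditioningStack, dict[str, Raster]]:
    """All conditioning factors and ancillary layers from terrain + hydrography.

    Construction rules (all seeded):

    * precipitation = base + lapse * elevation + correlated noise;
    * NDVI rises with precipitation, drops near built-up and on bare rock;
    * land cover by a threshold cascade over elevation/slope/NDVI;
    * lithology is a Voronoi mosaic over 5 seeded centers;
    * population concentrates at low elevation and low slope;
    * NPP is positively coupled to NDVI; ET consumes part of precipitation;
    * rainfall erosivity scales with precipitation, erodibility with lithology.

    Returns the ConditioningStack plus a dict of ancillary rasters
    (population, npp, evapotranspiration, rainfall_erosivity, soil_erodibility).
    """
    g = elevation.grid
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 23]))
    z = elevation.values
    relief = max(config.relief_amplitude, 1.0)
    elev01 = z / relief

    slope_r, aspect_r = horn_slope_aspect(elevation)
    slope = slope_r.values

    precip = (
        config.precip_base
        + config.precip_lapse * z
        + config.precip_noise_sd * _correlated_noise(rng, g.shape, 8.0)
    )
    precip = np.clip(precip, 0.0, None)

    river = river_mask.codes == 1
    builtup_seed = _correlated_noise(rng, g.shape, 12.0)

    p01 = (precip - precip.min()) / max(np.ptp(precip), 1e-9)
    ndvi = 0.15 + 0.6 * p01 + 0.15 * _correlated_noise(rng, g.shape, 5.0)
    # suppress vegetation where development will sit (low, flat, high noise)
    ndvi -= 0.35 * ((elev01 < 0.25) & (slope < 8) & (builtup_seed > 0.8))
    ndvi = np.clip(ndvi, 0.0, 0.95)  # dense canopy saturates below 1

    if config.landcover_rules is None:
        landuse_codes = _classify_landcover(elev01, slope, ndvi, river, builtup_seed)
    else:
        landuse_codes = np.zeros(g.shape, dtype=np.int64)
        unassigned = np.ones(g.shape, dtype=bool)
        landuse_codes[river] = 5
        unassigned &= ~river
        for code, predicate in config.landcover_rules:
            hit = unassigned & np.asarray(predicate(elev01, slope, ndvi, builtup_seed), bool)
            landuse_codes[hit] = int(code)
            unassigned &= ~hit
        if unassigned.any():
            e = elev01[unassigned]
            s = slope[unassigned]
            raise ValueError(
                "landcover_rules do not cover the domain: "
                f"{int(unassigned.sum())} cells unassigned, elevation01 in "
                f"[{e.min():.2f}, {e.max():.2f}], slope in [{s.min():.1f}, {s.max():.1f}] deg"
            )
    landuse = CategoricalRaster(g, landuse_codes, dict(LANDCOVER_LEGEND))

    # lithology: Voronoi mosaic over 5 seeded centers
    centers = rng.uniform(0, 1, size=(5, 2)) * [g.n_rows, g.n_cols]
    rr, cc = np.mgrid[0 : g.n_rows, 0 : g.n_cols]
    d2 = [(rr - cy) ** 2 + (cc - cx) ** 2 for cy, cx in centers]
    lith_codes = np.argmin(np.stack(d2), axis=0).astype(np.int64) + 1
    lithology = CategoricalRaster(g, lith_codes, dict(LITHOLOGY_LEGEND))

    dist_fault = distance_raster(list(faults), g)
    dist_river = distance_raster(list(rivers), g)

    stack = ConditioningStack(
        elevation=elevation,
        slope=slope_r,
        precipitation=Raster(g, precip),
        ndvi=Raster(g, ndvi),
        aspect=aspect_sectors(aspect_r),
        landuse=landuse,
        lithology=lithology,
        dist_fault=dist_fault,
        dist_river=dist_river,
    )

    # ancillary layers
    lowland = np.exp(-3.0 * elev01) * np.exp(-slope / 10.0)
    pop = config.population_scale * lowland * rng.lognormal(0.0, 0.5, g.shape)
    pop *= 1.0 + 9.0 * (landuse_codes == 6)
    pop[river] = 0.0

    npp = np.clip(900.0 * ndvi + 80.0 * _correlated_noise(rng, g.shape, 5.0), 0.0, None)
    et = np.clip(precip * (0.35 + 0.2 * ndvi) + 30.0 * _correlated_noise(rng, g.shape, 6.0), 0.0, None)
    erosivity = np.clip(8.0 * precip - 4000.0, 500.0, None)  # MJ*mm/(hm^2*h*a), rough scaling
    erod_by_lith = np.array([0.0, 0.015, 0.022, 0.028, 0.035, 0.045])  # index by code
    erodibility = erod_by_lith[lith_codes] * np.clip(
        1.0 + 0.15 * _correlated_noise(rng, g.shape, 10.0), 0.5, 1.5
    )

    ancillary = {
        "population": Raster(g, pop),
        "npp": Raster(g, npp),
        "evapotranspiration": Raster(g, et),
        "rainfall_erosivity": Raster(g, erosivity),
        "soil_erodibility": Raster(g, erodibility),
    }
    return stack, ancillary


# ---------------------------------------------------------------------------
# planted disasters


def planted_probability(stack: ConditioningStack, model: PlantedHazardModel) -> Raster:
    """Per-cell logistic event probability under the planted model."""
    g = stack.grid
    score = np.full(g.shape, model.intercept, dtype=float)
    for name, w in model.factor_weights.items():
        layer = stack.layer(name)
        if isinstance(layer, CategoricalRaster):
            vals = layer.codes.astype(float)
        else:
            vals = layer.values
        rng_span = np.ptp(vals)
        z = (vals - vals.min()) / rng_span if rng_span > 0 else np.zeros_like(vals)
        score += w * z
    prob = 1.0 / (1.0 + np.exp(-score))
    return Raster(g, prob, stack.nodata_mask())


def plant_disasters(
    stack: ConditioningStack,
    model: PlantedHazardModel,
    seed: int,
) -> np.ndarray:
    """Draw the disaster inventory from the planted logistic process.

    ``n_events`` distinct cells are sampled with probability proportional to
    the logistic score; each event sits at its cell center jittered uniformly
    within the cell.  Returns an (n_events, 2) coordinate array.
    """
    g = stack.grid
    prob = planted_probability(stack, model).values.ravel().copy()
    prob[stack.nodata_mask().ravel()] = 0.0
    n_pos = int(np.count_nonzero(prob))
    if model.n_events > n_pos:
        raise ValueError(
            f"n_events={model.n_events} exceeds the {n_pos} cells with nonzero probability"
        )
    if model.n_events == 0:
        return np.empty((0, 2))
    rng = np.random.default_rng(np.random.SeedSequence([seed, 37]))
    idx = rng.choice(prob.size, size=model.n_events, replace=False, p=prob / prob.sum())
    rows, cols = np.unravel_index(idx, g.shape)
    jitter = rng.uniform(-0.5, 0.5, size=(model.n_events, 2))
    x = g.origin_x + (cols + 0.5 + jitter[:, 0]) * g.cell_size
    y = g.origin_y - (rows + 0.5 + jitter[:, 1]) * g.cell_size
    return np.column_stack([x, y])


# ---------------------------------------------------------------------------
# one-call region builder


def generate_region(
    config: RegionConfig | None = None,
    model: PlantedHazardModel | None = None,
) -> SyntheticRegion:
    """Generate the full synthetic region: terrain, hydrography, all factor
    and ancillary layers, and the planted disaster inventory."""
    config = config or RegionConfig()
    model = model or PlantedHazardModel()
    elevation = generate_terrain(config)
    rivers, river_mask, faults = derive_hydrofeatures(elevation, config)
    stack, ancillary = generate_covariates(elevation, rivers, river_mask, faults, config)
    events = plant_disasters(stack, model, config.seed)
    return SyntheticRegion(
        config=config,
        stack=stack,
        rivers=rivers,
        faults=faults,
        river_mask=river_mask,
        population=ancillary["population"],
        npp=ancillary["npp"],
        evapotranspiration=ancillary["evapotranspiration"],
        rainfall_erosivity=ancillary["rainfall_erosivity"],
        soil_erodibility=ancillary["soil_erodibility"],
        events_xy=events,
        planted_model=model,
        true_probability=planted_probability(stack, model),
    )
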