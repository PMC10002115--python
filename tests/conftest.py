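import numpy as np
import pytest

from ecorisk.grid import CategoricalRaster, GridSpec, Raster
from ecorisk.synthetic import PlantedHazardModel, RegionConfig, generate_region


@pytest.fixture
def grid10() -> GridSpec:
    return GridSpec(10, 10, 30.0, origin_x=0.0, origin_y=300.0, crs_tag="EPSG:32650")


@pytest.fixture
def ramp_raster(grid10) -> Raster:
    """Values linear in the x coordinate of the cell center."""
    x, _ = grid10.cell_centers()
    return Raster(grid10, 2.0 * x + 5.0)


def make_categorical(codes: np.ndarray, cell_size: float = 30.0) -> CategoricalRaster:
    codes = np.asarray(codes, dtype=np.int64)
    grid = GridSpec(codes.shape[0], codes.shape[1], cell_size, 0.0, codes.shape[0] * cell_size)
    legend = {int(c): f"class {int(c)}" for c in np.unique(codes)}
    return CategoricalRaster(grid, codes, legend)


@pytest.fixture(scope="session")
def small_region():
    """One deterministic 64x64 synthetic region shared by read-only tests."""
    cfg = RegionConfig(
        grid=GridSpec(64, 64, 30.0, 500_000.0, 3_000_000.0, "EPSG:32650"),
        seed=7,
    )
    model = PlantedHazardModel(n_events=150)
    return generate_region(cfg, model)
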