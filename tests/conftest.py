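import numpy as np
import pytest

from paleosdm import (
    ClimateGrid, GridGeometry, ScenarioSpec, VirtualSpecies,
    draw_background, extract_env, fit_maxent, generate_climate_stack,
    sample_occurrences,
)


@pytest.fixture(scope="session")
def gauss_species():
    """A virtual species with a niche near the default field means."""
    return VirtualSpecies("vs1", (26.0, 16.0, 700.0, 120.0),
                          (2.4, 3.2, 200.0, 64.0))


@pytest.fixture(scope="session")
def small_stack():
    """40x40, 6-slice drifted stack under default variables."""
    spec = ScenarioSpec(nrows=40, ncols=40, n_slices=6, seed=101)
    return generate_climate_stack(spec)


@pytest.fixture(scope="session")
def slice0(small_stack):
    return small_stack[0]


@pytest.fixture(scope="session")
def fitted_maxent(gauss_species, slice0):
    occ = sample_occurrences(gauss_species, slice0, 150, seed=11)
    pe = extract_env(occ.points, slice0)
    bg = draw_background(slice0, 500, seed=12)
    be = extract_env(bg.points, slice0)
    return fit_maxent(pe, be), occ


@pytest.fixture()
def tiny_grid():
    """4x5 two-variable grid with one nodata cell, hand-checkable."""
    geom = GridGeometry(west=0.0, north=4.0, cell_size=1.0, nrows=4, ncols=5)
    rng = np.random.default_rng(0)
    t = rng.uniform(10, 30, size=(4, 5))
    pr = rng.uniform(0, 500, size=(4, 5))
    nodata = np.zeros((4, 5), dtype=bool)
    nodata[0, 0] = True
    return ClimateGrid(geometry=geom, variables={"temp": t, "prec": pr},
                       nodata_mask=nodata, age=0)
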