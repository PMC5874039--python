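"""Virtual species and virtual paleoclimate generation.

Every downstream stage of the pipeline (cleaning, model fitting, hindcasts,
fossil assignment) can be exercised against known ground truth by simulating

* a stack of four partially correlated, spatially smooth bioclim-like fields
  on a regular lon/lat grid, one slice per kyr BP, drifting linearly back in
  time (an idealisation of interpolated millennial paleoclimate layers);
* species with Gaussian climatic niches of known centre and width;
* presence samples drawn from a species' true suitability at the present
  slice; and
* fossils planted at cells known to be climatically suitable at a past
  slice (optionally unsuitable today, emulating records found far outside a
  species' current range).

Determinism: every operation is a pure function of its spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .assignment import FossilRecord
from .grids import ClimateGrid, ClimateStack, GridGeometry, OccurrenceSet

__all__ = [
    "VirtualSpecies",
    "VariableSpec",
    "ScenarioSpec",
    "true_suitability",
    "true_suitability_grid",
    "generate_climate_stack",
    "sample_occurrences",
    "plant_fossil",
    "plant_decoy_fossil",
    "DEFAULT_VARIABLES",
]


@dataclass(frozen=True)
class VirtualSpecies:
    """A species with a known Gaussian climatic niche.

    Suitability of an environment ``e`` is
    ``max_suitability * exp(-0.5 * sum_j ((e_j - center_j) / width_j)**2)``,
    i.e. a bell response per variable with optimum ``niche_center`` and
    tolerance ``niche_width``; the climatic niche is assumed fixed through
    the modelled time span (niche conservatism).
    """

    species_id: str
    niche_center: tuple[float, ...]
    niche_width: tuple[float, ...]
    max_suitability: float = 1.0

    def __post_init__(self) -> None:
        if len(self.niche_center) != len(self.niche_width):
            raise ValueError("niche_center and niche_width lengths differ")
        if any(w <= 0 for w in self.niche_width):
            raise ValueError("niche_width must be strictly positive")
        if not (0 < self.max_suitability <= 1):
            raise ValueError("max_suitability must lie in (0, 1]")


@dataclass(frozen=True)
class VariableSpec:
    """One simulated climate variable.

    ``mean``/``scale`` set the present-day spatial mean and standard
    deviation (variable units); ``gradient`` is the direction of the fixed
    linear spatial trend ("ns" north-south or "ew" east-west);
    ``non_negative`` clips the field at 0 (precipitation-like variables).
    """

    name: str
    mean: float
    scale: float
    gradient: str = "ns"
    non_negative: bool = False


#: Default study conditions: four bioclim-like variables (temperature of the
#: warmest/coldest quarter in deg C, precipitation of the wettest/driest
#: quarter in mm).
DEFAULT_VARIABLES: tuple[VariableSpec, ...] = (
    VariableSpec("bio10", 26.0, 3.0, "ns"),
    VariableSpec("bio11", 16.0, 4.0, "ns"),
    VariableSpec("bio16", 700.0, 250.0, "ew", non_negative=True),
    VariableSpec("bio17", 120.0, 80.0, "ew", non_negative=True),
)

#: Default per-kyr drift going back in time: cooler and drier towards the
#: last glacial maximum (roughly -5 deg C and -40% wet-quarter precipitation
#: by 21 kyr BP).
DEFAULT_DRIFT: tuple[float, ...] = (-0.25, -0.3, -12.0, -2.5)


@dataclass
class ScenarioSpec:
    """Full description of a synthetic study scenario."""

    nrows: int = 60
    ncols: int = 60
    west: float = -70.0
    north: float = 0.0
    cell_size: float = 0.25
    n_slices: int = 22
    variables: tuple[VariableSpec, ...] = DEFAULT_VARIABLES
    drift: tuple[float, ...] = DEFAULT_DRIFT
    inter_variable_correlation: float = 0.3
    species: list[VirtualSpecies] = field(default_factory=list)
    n_occurrences: int = 100
    nodata_border: int = 0
    smooth_sigma: float = 2.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nrows < 1 or self.ncols < 1:
            raise ValueError("grid dimensions must be positive")
        if self.nrows * self.ncols < 4:
            raise ValueError("grid must have at least 4 cells")
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")
        if self.n_occurrences < 1:
            raise ValueError("n_occurrences must be >= 1")
        if len(self.drift) != len(self.variables):
            raise ValueError("drift must give one rate per variable")
        rho = self.inter_variable_correlation
        if not (-1.0 <= rho <= 1.0):
            raise ValueError("inter_variable_correlation must be in [-1, 1]")

    @property
    def geometry(self) -> GridGeometry:
        return GridGeometry(self.west, self.north, self.cell_size,
                            self.nrows, self.ncols)

    @property
    def var_names(self) -> list[str]:
        return [v.name for v in self.variables]


def four_species_scenario(seed: int = 0, n_occurrences: int = 150) -> ScenarioSpec:
    """Bundled four-candidate study scenario.

    Four species separated on the warm-quarter temperature and wet-quarter
    precipitation axes (narrow tolerance there, broad tolerance on the
    other two variables), on a 50x50 grid with 13 slices of glacial-style
    cooling/drying drift. Species ``sp_a`` occupies the cool-dry corner:
    under the drift its past range is displaced into cells that are
    unsuitable today, so a fossil planted for it at a late slice lies
    outside its current range — the configuration of the headline
    identity-recovery experiment. Pairwise niche-centre separation is at
    least twice the sum of the two species' widths on a separating axis.
    """
    widths = (1.5, 8.0, 100.0, 160.0)
    species = [
        VirtualSpecies("sp_a", (22.5, 16.0, 425.0, 120.0), widths),
        VirtualSpecies("sp_b", (22.5, 16.0, 875.0, 120.0), widths),
        VirtualSpecies("sp_c", (28.5, 16.0, 425.0, 120.0), widths),
        VirtualSpecies("sp_d", (28.5, 16.0, 875.0, 120.0), widths),
    ]
    return ScenarioSpec(nrows=50, ncols=50, n_slices=13,
                        drift=(-0.45, -0.5, -20.0, -4.5), species=species,
                        n_occurrences=n_occurrences, seed=seed)


def two_species_scenario(seed: int = 0, n_occurrences: int = 100) -> ScenarioSpec:
    """Smaller two-candidate variant for end-to-end demonstrations."""
    full = four_species_scenario(seed=seed, n_occurrences=n_occurrences)
    return ScenarioSpec(nrows=40, ncols=40, n_slices=11,
                        drift=full.drift, species=full.species[:2],
                        n_occurrences=n_occurrences, seed=seed)


def scenario_from_dict(d: dict) -> ScenarioSpec:
    """Build a :class:`ScenarioSpec` from a plain (YAML-friendly) mapping.

    Recognized keys mirror the dataclass fields; ``variables`` entries are
    mappings with name/mean/scale/gradient/non_negative, ``species`` entries
    mappings with species_id/niche_center/niche_width/max_suitability.
    """
    d = dict(d)
    if "variables" in d:
        d["variables"] = tuple(VariableSpec(**v) for v in d["variables"])
    if "species" in d:
        d["species"] = [
            VirtualSpecies(
                species_id=s["species_id"],
                niche_center=tuple(s["niche_center"]),
                niche_width=tuple(s["niche_width"]),
                max_suitability=s.get("max_suitability", 1.0),
            )
            for s in d["species"]
        ]
    if "drift" in d:
        d["drift"] = tuple(d["drift"])
    d.pop("fossils", None)  # handled by the caller (CLI simulate)
    return ScenarioSpec(**d)


def true_suitability(species: VirtualSpecies, env: np.ndarray) -> np.ndarray:
    """Gaussian-niche suitability of environment vector(s).

    ``env`` is a single vector of one value per niche dimension, or an
    ``(n, p)`` array of such vectors. Returns values in
    ``[0, max_suitability]``; the optimum is attained exactly at the niche
    centre.
    """
    env = np.asarray(env, dtype=float)
    p = len(species.niche_center)
    if env.shape[-1] != p:
        raise ValueError(
            f"environment has {env.shape[-1]} dimensions, niche has {p}"
        )
    z = (env - np.asarray(species.niche_center)) / np.asarray(species.niche_width)
    out = species.max_suitability * np.exp(-0.5 * np.sum(z * z, axis=-1))
    return out


def true_suitability_grid(species: VirtualSpecies, grid: ClimateGrid) -> np.ndarray:
    """True suitability at every cell of a climate grid (NaN on nodata)."""
    env = np.stack([grid.variables[n] for n in grid.var_names], axis=-1)
    suit = true_suitability(species, env)
    suit = np.where(grid.nodata_mask, np.nan, suit)
    return suit


def _standardize(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std()


def _gradient_surface(geom: GridGeometry, direction: str) -> np.ndarray:
    if direction == "ns":
        g = np.tile(np.linspace(1.0, -1.0, geom.nrows)[:, None], (1, geom.ncols))
    elif direction == "ew":
        g = np.tile(np.linspace(-1.0, 1.0, geom.ncols)[None, :], (geom.nrows, 1))
    else:
        raise ValueError(f"unknown gradient direction {direction!r}")
    return _standardize(g)


def _correlated_latents(spec: ScenarioSpec, rng: np.random.Generator) -> np.ndarray:
    """Standardized smooth random fields with target pairwise correlation.

    Smooth fields carry few effective degrees of freedom, so their sample
    correlations scatter widely; the raw latents are therefore whitened
    against their *realized* covariance before coloring with the target
    correlation matrix, pinning the realized pairwise correlation of the
    latents to the target exactly.
    """
    p = len(spec.variables)
    shape = (spec.nrows, spec.ncols)
    # Orthogonalize against both gradient directions so the deterministic
    # gradient term added later cannot leak into the latent correlations.
    basis = [
        _gradient_surface(spec.geometry, "ns").ravel(),
        _gradient_surface(spec.geometry, "ew").ravel(),
    ]
    lat = np.empty((p,) + shape)
    for j in range(p):
        smooth = _standardize(gaussian_filter(rng.standard_normal(shape),
                                              spec.smooth_sigma, mode="nearest"))
        white = rng.standard_normal(shape)
        z = _standardize(0.85 * smooth + 0.15 * white).ravel()
        for g in basis:
            z = z - (z @ g) / (g @ g) * g
        lat[j] = _standardize(z.reshape(shape))
    rho = spec.inter_variable_correlation
    target = np.full((p, p), rho)
    np.fill_diagonal(target, 1.0)
    try:
        chol = np.linalg.cholesky(target)
    except np.linalg.LinAlgError:
        raise ValueError(
            f"inter_variable_correlation={rho} does not yield a valid "
            f"{p}x{p} correlation matrix"
        ) from None
    flat = lat.reshape(p, -1)
    emp = np.corrcoef(flat)
    evals, evecs = np.linalg.eigh(emp)
    whiten = evecs @ np.diag(1.0 / np.sqrt(np.maximum(evals, 1e-12))) @ evecs.T
    mixed = (chol @ whiten @ flat).reshape(p, *shape)
    for j in range(p):
        mixed[j] = _standardize(mixed[j])
    return mixed


def generate_climate_stack(spec: ScenarioSpec) -> ClimateStack:
    """Simulate the full paleoclimate stack of a scenario.

    Each variable's present-day (slice 0) field is the sum of a fixed linear
    spatial gradient, a seeded smooth low-frequency surface and seeded white
    noise, scaled to the variable's spatial mean and standard deviation.
    Slice ``k`` (k kyr BP) shifts the field mean by ``k * drift_j``;
    precipitation-like variables are then clipped at 0. Identical seeds give
    bit-identical stacks.
    """
    geom = spec.geometry
    rng = np.random.Generator(np.random.PCG64(spec.seed))
    latents = _correlated_latents(spec, rng)

    # Gradient weight 0.3 keeps the realized pairwise correlation within
    # 0.09 of the target while giving the fields large-scale structure.
    w_grad, w_lat = 0.3, np.sqrt(1 - 0.3**2)
    base = {}
    for j, var in enumerate(spec.variables):
        g = _gradient_surface(geom, var.gradient)
        field0 = var.mean + var.scale * (w_grad * g + w_lat * latents[j])
        base[var.name] = field0

    b = spec.nodata_border
    nodata = np.zeros(geom.shape, dtype=bool)
    if b > 0:
        nodata[:] = True
        nodata[b:-b or None, b:-b or None] = False

    slices = {}
    for k in range(spec.n_slices):
        variables = {}
        for j, var in enumerate(spec.variables):
            f = base[var.name] + k * spec.drift[j]
            if var.non_negative:
                f = np.clip(f, 0.0, None)
            variables[var.name] = f
        slices[k] = ClimateGrid(geometry=geom, variables=variables,
                                nodata_mask=nodata.copy(), age=k)
    return ClimateStack(slices)


def sample_occurrences(species: VirtualSpecies, slice0: ClimateGrid,
                       n: int, seed: int) -> OccurrenceSet:
    """Draw presence cells proportional to true suitability at slice 0.

    ``n`` distinct cells are drawn without replacement with probability
    proportional to the species' true suitability at each valid cell; points
    are reported at cell centres. Cells with zero suitability are never
    sampled.
    """
    suit = true_suitability_grid(species, slice0)
    flat = np.nan_to_num(suit, nan=0.0).ravel()
    positive = np.nonzero(flat > 0)[0]
    if n > positive.size:
        raise ValueError(
            f"requested {n} occurrences but only {positive.size} cells have "
            f"positive suitability (shortfall of {n - positive.size})"
        )
    p = flat[positive] / flat[positive].sum()
    rng = np.random.Generator(np.random.PCG64(seed))
    chosen = rng.choice(positive, size=n, replace=False, p=p)
    rows, cols = np.unravel_index(chosen, slice0.geometry.shape)
    lon, lat = slice0.geometry.cell_center(rows, cols)
    pts = np.column_stack([lon, lat])
    return OccurrenceSet(species_id=species.species_id, points=pts,
                         provenance="synthetic: true-niche sample")


def plant_fossil(species: VirtualSpecies, stack: ClimateStack,
                 target_slice: int, require_outside_current: bool = True,
                 seed: int = 0, fossil_id: str | None = None) -> FossilRecord:
    """Plant a fossil at a cell suitable for the species at a past slice.

    The chosen cell has true suitability at ``target_slice`` of at least
    half the species' maximum; with ``require_outside_current`` it must in
    addition be nearly unsuitable today (below 10% of maximum at slice 0),
    emulating a fossil found outside the species' present range. The age
    interval spans +/-100 years around the nominal slice age, mimicking a
    calibrated-date range.
    """
    grid_t = stack[target_slice]
    suit_t = np.nan_to_num(true_suitability_grid(species, grid_t), nan=0.0)
    ok = suit_t >= 0.5 * species.max_suitability
    if require_outside_current:
        suit_0 = np.nan_to_num(true_suitability_grid(species, stack[0]), nan=0.0)
        ok &= suit_0 < 0.1 * species.max_suitability
    idx = np.nonzero(ok.ravel())[0]
    if idx.size == 0:
        raise ValueError(
            "no cell is suitable at the target slice"
            + (" while unsuitable at present" if require_outside_current else "")
            + "; increase the scenario's climate drift or relax the constraint"
        )
    rng = np.random.Generator(np.random.PCG64(seed))
    cell = int(rng.choice(idx))
    row, col = np.unravel_index(cell, grid_t.geometry.shape)
    lon, lat = grid_t.geometry.cell_center(row, col)
    return FossilRecord(
        fossil_id=fossil_id or f"fossil_{species.species_id}_{target_slice}kyr",
        lon=float(lon), lat=float(lat),
        age_min_bp=target_slice * 1000 - 100,
        age_max_bp=target_slice * 1000 + 100,
        candidates=[],
    )


def plant_decoy_fossil(species: VirtualSpecies, stack: ClimateStack,
                       target_slice: int, max_fraction: float = 0.001,
                       seed: int = 0, fossil_id: str | None = None) -> FossilRecord:
    """Plant a fossil at a cell never suitable for the species at any slice.

    Adversarial counterpart of :func:`plant_fossil` used to check that
    model-based validation *fails* where it should: the chosen cell's true
    suitability stays below ``max_fraction`` of the species' maximum in
    every slice of the stack, and its environment at ``target_slice`` lies
    inside the present-day range of every variable (an analogue climate,
    so the verdict reflects the species' tolerance rather than
    extrapolation/clamping artefacts at a climate no model has seen).
    """
    geom = stack.geometry
    worst = np.zeros(geom.shape)
    for age in stack.ages:
        s = np.nan_to_num(true_suitability_grid(species, stack[age]), nan=0.0)
        worst = np.maximum(worst, s)
    ok = worst < max_fraction * species.max_suitability
    ok &= stack[0].valid_mask
    grid0, grid_t = stack[0], stack[target_slice]
    for name in stack.var_names:
        now = grid0.variables[name][grid0.valid_mask]
        ok &= ((grid_t.variables[name] >= now.min())
               & (grid_t.variables[name] <= now.max()))
    idx = np.nonzero(ok.ravel())[0]
    if idx.size == 0:
        raise ValueError("every cell is suitable at some slice; no decoy possible")
    rng = np.random.Generator(np.random.PCG64(seed))
    cell = int(rng.choice(idx))
    row, col = np.unravel_index(cell, geom.shape)
    lon, lat = geom.cell_center(row, col)
    return FossilRecord(
        fossil_id=fossil_id or f"decoy_{species.species_id}_{target_slice}kyr",
        lon=float(lon), lat=float(lat),
        age_min_bp=target_slice * 1000 - 100,
        age_max_bp=target_slice * 1000 + 100,
        candidates=[],
    )
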