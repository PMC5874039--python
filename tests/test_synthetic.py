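"""Virtual species / virtual paleoclimate generator: ground-truth contracts."""

import numpy as np
import pytest

from paleosdm import (
    ScenarioSpec, VirtualSpecies, generate_climate_stack, plant_decoy_fossil,
    plant_fossil, sample_occurrences, true_suitability, true_suitability_grid,
)
from paleosdm.synthetic import four_species_scenario


class TestTrueSuitability:
    def test_center_attains_max(self, gauss_species):
        s = true_suitability(gauss_species, np.array(gauss_species.niche_center))
        assert s == pytest.approx(gauss_species.max_suitability)

    def test_one_width_from_center(self, gauss_species):
        env = np.array(gauss_species.niche_center, dtype=float)
        env[2] += gauss_species.niche_width[2]
        s = true_suitability(gauss_species, env)
        assert s == pytest.approx(
            gauss_species.max_suitability * np.exp(-0.5), rel=1e-12)

    def test_matches_direct_formula_on_random_env(self, gauss_species):
        rng = np.random.default_rng(3)
        env = rng.normal(size=(50, 4)) * [3, 4, 250, 80] + [26, 16, 700, 120]
        got = true_suitability(gauss_species, env)
        # independent elementwise re-evaluation
        for i in range(len(env)):
            z2 = sum(((env[i, j] - gauss_species.niche_center[j])
                      / gauss_species.niche_width[j]) ** 2 for j in range(4))
            assert got[i] == pytest.approx(np.exp(-0.5 * z2), rel=1e-12)
        assert np.all((got >= 0) & (got <= 1))

    def test_symmetry_about_center(self, gauss_species):
        c = np.array(gauss_species.niche_center, dtype=float)
        up, down = c.copy(), c.copy()
        up[0] += 1.7
        down[0] -= 1.7
        assert true_suitability(gauss_species, up) == pytest.approx(
            true_suitability(gauss_species, down), rel=1e-12)

    def test_dimension_mismatch_errors(self, gauss_species):
        with pytest.raises(ValueError):
            true_suitability(gauss_species, np.zeros(3))

    def test_invalid_species(self):
        with pytest.raises(ValueError):
            VirtualSpecies("x", (1.0, 2.0), (1.0, -1.0))
        with pytest.raises(ValueError):
            VirtualSpecies("x", (1.0,), (1.0,), max_suitability=0.0)


class TestGenerateClimateStack:
    def test_zero_drift_slices_identical(self):
        spec = ScenarioSpec(nrows=20, ncols=20, n_slices=4,
                            drift=(0.0, 0.0, 0.0, 0.0), seed=5)
        stack = generate_climate_stack(spec)
        g0 = stack[0]
        for age in stack.ages[1:]:
            for v in g0.var_names:
                np.testing.assert_array_equal(stack[age].variables[v],
                                              g0.variables[v])

    def test_same_seed_bit_identical(self):
        spec = ScenarioSpec(nrows=25, ncols=20, n_slices=3, seed=7)
        a, b = generate_climate_stack(spec), generate_climate_stack(spec)
        for age in a.ages:
            for v in a[age].var_names:
                np.testing.assert_array_equal(a[age].variables[v],
                                              b[age].variables[v])

    def test_drift_linearity_of_slice_means(self):
        # temperature drift of 0.5 deg/kyr over 5 slices: mean shift = 2.0.
        # Precip scales kept small so the non-negativity clip never binds
        # (clipping would legitimately bend the mean trajectory).
        from paleosdm.synthetic import VariableSpec
        variables = (
            VariableSpec("bio10", 26.0, 3.0, "ns"),
            VariableSpec("bio11", 16.0, 4.0, "ns"),
            VariableSpec("bio16", 700.0, 50.0, "ew", non_negative=True),
            VariableSpec("bio17", 300.0, 30.0, "ew", non_negative=True),
        )
        spec = ScenarioSpec(nrows=30, ncols=30, n_slices=5,
                            variables=variables,
                            drift=(0.5, 0.2, 5.0, 1.0), seed=2)
        stack = generate_climate_stack(spec)
        m0 = stack[0].variables["bio10"].mean()
        m4 = stack[4].variables["bio10"].mean()
        assert m4 - m0 == pytest.approx(2.0, rel=1e-6)
        for k in stack.ages:
            for j, v in enumerate(stack.var_names):
                delta = stack[k].variables[v].mean() - stack[0].variables[v].mean()
                assert delta == pytest.approx(k * spec.drift[j], abs=1e-9)

    def test_precipitation_non_negative(self):
        spec = ScenarioSpec(nrows=30, ncols=30, n_slices=22, seed=9)
        stack = generate_climate_stack(spec)
        for age in stack.ages:
            assert stack[age].variables["bio17"].min() >= 0
            assert stack[age].variables["bio16"].min() >= 0

    def test_correlation_near_target_on_large_grid(self):
        for seed in (1, 2):
            spec = ScenarioSpec(nrows=50, ncols=50, n_slices=1,
                                inter_variable_correlation=0.3, seed=seed)
            g = generate_climate_stack(spec)[0]
            arrs = [g.variables[v].ravel() for v in g.var_names]
            for i in range(4):
                for j in range(i + 1, 4):
                    r = np.corrcoef(arrs[i], arrs[j])[0, 1]
                    assert abs(r - 0.3) < 0.15, (seed, i, j, r)

    def test_nodata_border(self):
        spec = ScenarioSpec(nrows=10, ncols=12, n_slices=1, nodata_border=2,
                            seed=0)
        g = generate_climate_stack(spec)[0]
        assert g.nodata_mask[0, :].all() and g.nodata_mask[:, -1].all()
        assert not g.nodata_mask[2:-2, 2:-2].any()

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            ScenarioSpec(nrows=0, ncols=10)
        with pytest.raises(ValueError):
            ScenarioSpec(nrows=1, ncols=2)  # < 4 cells
        with pytest.raises(ValueError):
            ScenarioSpec(n_slices=0)


class TestSampleOccurrences:
    def test_exactly_n_unique_cells(self, gauss_species, slice0):
        occ = sample_occurrences(gauss_species, slice0, 120, seed=4)
        assert len(occ) == 120
        assert len({tuple(p) for p in occ.points}) == 120

    def test_deterministic(self, gauss_species, slice0):
        a = sample_occurrences(gauss_species, slice0, 50, seed=8)
        b = sample_occurrences(gauss_species, slice0, 50, seed=8)
        np.testing.assert_array_equal(a.points, b.points)

    def test_zero_suitability_never_sampled(self, slice0):
        # extremely narrow niche: suitability underflows to 0 away from it
        sp = VirtualSpecies("narrow", (26.0, 16.0, 700.0, 120.0),
                            (1e-3, 1e-3, 1e-3, 1e-3))
        suit = true_suitability_grid(sp, slice0)
        n_pos = int(np.nansum(suit > 0))
        with pytest.raises(ValueError, match="positive suitability"):
            sample_occurrences(sp, slice0, n_pos + 1, seed=0)

    def test_sampling_frequency_tracks_suitability(self):
        spec = ScenarioSpec(nrows=50, ncols=50, n_slices=1, seed=3)
        g = generate_climate_stack(spec)[0]
        sp = VirtualSpecies("vs", (26.0, 16.0, 700.0, 120.0),
                            (3.0, 4.0, 250.0, 80.0))
        suit = np.nan_to_num(true_suitability_grid(sp, g), nan=0.0).ravel()
        counts = np.zeros(suit.size)
        n = 2000
        for rep in range(25):
            occ = sample_occurrences(sp, g, n, seed=1000 + rep)
            rows, cols = g.geometry.cells_of(occ.points)
            np.add.at(counts, rows * g.geometry.ncols + cols, 1)
        from scipy.stats import spearmanr
        mask = suit > 0
        rho = spearmanr(counts[mask], suit[mask]).statistic
        assert rho > 0.8


class TestPlantFossil:
    def test_zero_drift_outside_current_impossible(self, gauss_species):
        spec = ScenarioSpec(nrows=20, ncols=20, n_slices=3,
                            drift=(0.0, 0.0, 0.0, 0.0), seed=1)
        stack = generate_climate_stack(spec)
        with pytest.raises(ValueError, match="drift|constraint"):
            plant_fossil(gauss_species, stack, 2,
                         require_outside_current=True, seed=0)

    def test_constraints_verified_by_direct_evaluation(self):
        spec = four_species_scenario(seed=3)
        stack = generate_climate_stack(spec)
        sp = spec.species[0]
        fossil = plant_fossil(sp, stack, 10, require_outside_current=True,
                              seed=3)
        row, col = stack.geometry.cell_of(fossil.lon, fossil.lat)
        past = true_suitability_grid(sp, stack[10])[row, col]
        present = true_suitability_grid(sp, stack[0])[row, col]
        assert past >= 0.5 * sp.max_suitability
        assert present < 0.1 * sp.max_suitability
        assert fossil.age_min_bp == 10 * 1000 - 100
        assert fossil.age_max_bp == 10 * 1000 + 100

    def test_without_outside_constraint_only_past_checked(self):
        spec = four_species_scenario(seed=3)
        stack = generate_climate_stack(spec)
        sp = spec.species[0]
        fossil = plant_fossil(sp, stack, 2, require_outside_current=False,
                              seed=5)
        row, col = stack.geometry.cell_of(fossil.lon, fossil.lat)
        past = true_suitability_grid(sp, stack[2])[row, col]
        assert past >= 0.5 * sp.max_suitability

    def test_decoy_is_never_suitable(self):
        spec = four_species_scenario(seed=4)
        stack = generate_climate_stack(spec)
        sp = spec.species[0]
        decoy = plant_decoy_fossil(sp, stack, 10, seed=4)
        row, col = stack.geometry.cell_of(decoy.lon, decoy.lat)
        for age in stack.ages:
            s = true_suitability_grid(sp, stack[age])[row, col]
            assert s < 0.001 * sp.max_suitability
        # decoy sits in analogue climate at the target slice
        g0, gt = stack[0], stack[10]
        for name in stack.var_names:
            now = g0.variables[name][g0.valid_mask]
            assert now.min() <= gt.variables[name][row, col] <= now.max()
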