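"""Fossil validation and candidate-species assignment."""

import numpy as np
import pandas as pd
import pytest

from paleosdm import (
    FossilRecord, OccurrenceSet, assign_fossil, draw_background, extract_env,
    fit_maxent, generate_climate_stack, min_occurrence_suitability,
    plant_fossil, sample_occurrences, slices_for_age, suitability_at_fossil,
    validate_against_fossil,
)
from paleosdm.grids import GridGeometry, SuitabilityMap
from paleosdm.synthetic import four_species_scenario


class TestSlicesForAge:
    """Frozen outputs of the documented rule: a +/-500-year window around
    the calibrated interval, with nearest-slice fallback."""

    AVAILABLE = list(range(0, 131))

    @pytest.mark.parametrize("interval,expected", [
        ((13898, 13941), [14]),   # 13,000 misses the 500-yr window
        ((11068, 11211), [11]),
        ((5000, 5001), [5]),
        ((21520, 22040), [22]),  # 21,000 lies 20 yr below the window
        ((19980, 20250), [20]),
    ])
    def test_window_rule(self, interval, expected):
        assert slices_for_age(interval, self.AVAILABLE) == expected

    def test_fallback_to_nearest_when_window_empty(self):
        assert slices_for_age((13898, 13941), [0, 10, 20]) == [14 - 4]
        assert slices_for_age((700, 800), [5, 10]) == [5]

    def test_result_never_empty(self):
        assert slices_for_age((99000, 99100), [0, 1, 2]) == [2]

    def test_empty_available_rejected(self):
        with pytest.raises(ValueError):
            slices_for_age((1000, 2000), [])


class TestMinOccurrenceSuitability:
    class _FixedModel:
        variable_names_ = None
        n_features_in_ = 4

        def __init__(self, table):
            self._table = table

        def predict_suitability(self, X, clamp=None):
            # score by lookup on the first variable
            key = np.round(np.asarray(X)[:, 0], 6)
            return np.array([self._table[k] for k in key])

    def test_minimum_over_occurrence_cells(self, slice0):
        geom = slice0.geometry
        rows, cols = np.array([5, 10, 20]), np.array([5, 10, 20])
        lon, lat = geom.cell_center(rows, cols)
        pts = np.column_stack([lon, lat])
        env = extract_env(pts, slice0)
        table = dict(zip(np.round(env.iloc[:, 0], 6), [0.2, 0.5, 0.9]))
        occ = OccurrenceSet("sp", pts)
        m = self._FixedModel(table)
        assert min_occurrence_suitability(m, occ, slice0) == \
            pytest.approx(0.2)

    def test_single_occurrence_returns_its_own(self, fitted_maxent, slice0):
        model, occ = fitted_maxent
        one = OccurrenceSet(occ.species_id, occ.points[:1])
        env = extract_env(one.points, slice0)
        assert min_occurrence_suitability(model, one, slice0) == \
            pytest.approx(float(model.predict_suitability(env)[0]))

    def test_empty_rejected(self, fitted_maxent, slice0):
        model, _ = fitted_maxent
        with pytest.raises(ValueError):
            min_occurrence_suitability(
                model, OccurrenceSet("sp", np.empty((0, 2))), slice0)


class TestSuitabilityAtFossil:
    def test_constant_map(self):
        geom = GridGeometry(0, 10, 1.0, 10, 10)
        m = SuitabilityMap(geometry=geom, values=np.full((10, 10), 0.3),
                           age=4)
        fossil = FossilRecord("f", 3.5, 6.5, 3900, 4100)
        assert suitability_at_fossil([m], fossil) == [pytest.approx(0.3)]

    def test_fossil_at_map_maximum(self, fitted_maxent, small_stack):
        from paleosdm import predict_map
        model, _ = fitted_maxent
        smap = predict_map(model, small_stack[0])
        r, c = np.unravel_index(np.nanargmax(smap.values),
                                smap.values.shape)
        lon, lat = small_stack.geometry.cell_center(r, c)
        fossil = FossilRecord("f", float(lon), float(lat), 0, 100)
        got = suitability_at_fossil([smap], fossil)[0]
        assert got == np.nanmax(smap.values)

    def test_nodata_slice_names_the_slice(self):
        geom = GridGeometry(0, 10, 1.0, 10, 10)
        vals = np.full((10, 10), np.nan)
        m = SuitabilityMap(geometry=geom, values=vals, age=7)
        fossil = FossilRecord("f7", 3.5, 6.5, 6900, 7100)
        with pytest.raises(ValueError, match="slice 7"):
            suitability_at_fossil([m], fossil)


@pytest.fixture(scope="module")
def planted_setup():
    """Four fitted candidates plus a fossil planted for species sp_a."""
    spec = four_species_scenario(seed=7)
    stack = generate_climate_stack(spec)
    slice0 = stack[0]
    cands = []
    for i, sp in enumerate(spec.species):
        occ = sample_occurrences(sp, slice0, spec.n_occurrences, seed=70 + i)
        pe = extract_env(occ.points, slice0)
        bg = draw_background(slice0, 1000, seed=170 + i)
        be = extract_env(bg.points, slice0)
        cands.append((sp.species_id, fit_maxent(pe, be), occ))
    fossil = plant_fossil(spec.species[0], stack, 10,
                          require_outside_current=True, seed=7)
    return spec, stack, cands, fossil


class TestAssignFossil:
    def test_planted_species_recovered_and_plausible(self, planted_setup):
        _, stack, cands, fossil = planted_setup
        rep = assign_fossil(cands, fossil, stack)
        assert rep.headline == "sp_a"
        row = next(r for r in rep.per_candidate if r.species == "sp_a")
        assert row.plausible
        assert rep.slices_evaluated == [10]

    def test_candidate_with_low_suitability_flagged_implausible(
            self, planted_setup):
        _, stack, cands, fossil = planted_setup
        rep = assign_fossil(cands, fossil, stack)
        for row in rep.per_candidate:
            assert row.plausible == (
                row.max_suitability >= row.min_current_suitability
                if row.min_current_suitability > 0
                else row.max_suitability > 0)

    def test_rows_independent_of_candidate_order(self, planted_setup):
        _, stack, cands, fossil = planted_setup
        a = assign_fossil(cands, fossil, stack)
        b = assign_fossil(list(reversed(cands)), fossil, stack)
        assert a.headline == b.headline
        assert a.ranking == b.ranking
        rows_a = {r.species: r for r in a.per_candidate}
        rows_b = {r.species: r for r in b.per_candidate}
        for sid in rows_a:
            assert rows_a[sid].max_suitability == rows_b[sid].max_suitability
            assert rows_a[sid].min_current_suitability == \
                rows_b[sid].min_current_suitability

    def test_adding_candidate_never_changes_others(self, planted_setup):
        _, stack, cands, fossil = planted_setup
        partial = assign_fossil(cands[:2], fossil, stack)
        full = assign_fossil(cands, fossil, stack)
        for r_partial in partial.per_candidate:
            r_full = next(r for r in full.per_candidate
                          if r.species == r_partial.species)
            assert r_full.max_suitability == r_partial.max_suitability
            assert r_full.min_current_suitability == \
                r_partial.min_current_suitability
            assert r_full.plausible == r_partial.plausible

    def test_single_candidate_degenerates_to_validation(self, planted_setup):
        _, stack, cands, fossil = planted_setup
        sid, model, occ = cands[0]
        rep = assign_fossil([cands[0]], fossil, stack)
        verdict = validate_against_fossil(model, occ, fossil, stack)
        assert verdict.passed == rep.per_candidate[0].plausible
        assert (rep.headline == sid) == verdict.passed

    def test_report_table_shape(self, planted_setup):
        _, stack, cands, fossil = planted_setup
        rep = assign_fossil(cands, fossil, stack)
        frame = rep.to_frame()
        assert set(frame["species"]) == {c[0] for c in cands}
        assert {"S", "m", "plausible", "ratio"} <= set(frame.columns)
        doc = rep.to_dict()
        assert doc["headline"] == rep.headline

    def test_no_candidates_rejected(self, planted_setup):
        _, stack, _, fossil = planted_setup
        with pytest.raises(ValueError):
            assign_fossil([], fossil, stack)


class TestValidateAgainstFossil:
    def test_planted_fossil_passes(self, planted_setup):
        _, stack, cands, fossil = planted_setup
        sid, model, occ = cands[0]
        verdict = validate_against_fossil(model, occ, fossil, stack)
        assert verdict.passed
        assert verdict.species == sid

    def test_never_suitable_cell_fails_without_error(self, planted_setup):
        from paleosdm import plant_decoy_fossil
        spec, stack, cands, _ = planted_setup
        decoy = plant_decoy_fossil(spec.species[0], stack, 10, seed=7)
        sid, model, occ = cands[0]
        verdict = validate_against_fossil(model, occ, decoy, stack)
        assert not verdict.passed

    def test_fossil_with_candidates_rejected(self, planted_setup):
        _, stack, cands, fossil = planted_setup
        sid, model, occ = cands[0]
        bad = FossilRecord("x", fossil.lon, fossil.lat, fossil.age_min_bp,
                           fossil.age_max_bp, candidates=["a", "b"])
        with pytest.raises(ValueError, match="candidate"):
            validate_against_fossil(model, occ, bad, stack)
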