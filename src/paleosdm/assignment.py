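"""Fossil-based model validation and taxonomic assignment.

The headline procedure: hindcast each candidate species' model to the
climate slices bracketing a fossil's calibrated age, read the suitability
at the fossil's cell, and compare it against that species' minimum
present-day suitability over its occurrence points (the weakest climate the
species demonstrably tolerates today). A candidate is *plausible* when the
hindcast suitability at the fossil reaches that minimum; plausible
candidates are ranked by hindcast suitability and the top one (if clearly
ahead) is the headline assignment. With a single known species and no
candidates the same comparison is a validation verdict for the model and
the paleoclimate layers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataprep import extract_env
from .grids import ClimateGrid, ClimateStack, OccurrenceSet, SuitabilityMap
from .projection import hindcast, mess

__all__ = [
    "FossilRecord",
    "AssignmentReport",
    "slices_for_age",
    "min_occurrence_suitability",
    "suitability_at_fossil",
    "assign_fossil",
    "validate_against_fossil",
]

#: Sentinel ratio reported when a species' minimum occurrence suitability is 0.
RATIO_SENTINEL = float("inf")


@dataclass
class FossilRecord:
    """A georeferenced, age-bracketed fossil specimen.

    ``candidates`` lists the species labels competing for the fossil's
    identity; an empty list means the identity is known (validation mode).
    Ages are calibrated years BP.
    """

    fossil_id: str
    lon: float
    lat: float
    age_min_bp: float
    age_max_bp: float
    candidates: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.age_min_bp < self.age_max_bp:
            raise ValueError("age_min_bp must be < age_max_bp")


def slices_for_age(interval: tuple[float, float],
                   available: list[int],
                   window_yr: float = 500.0) -> list[int]:
    """Climate slices matching a fossil's calibrated age interval.

    Returns every available slice ``k`` whose nominal age ``k*1000`` lies
    within ``[age_min - window, age_max + window]`` years BP. If the window
    catches no slice, falls back to the single slice nearest the interval
    midpoint, so the result is never empty.
    """
    if not available:
        raise ValueError("no climate slices available")
    lo, hi = interval
    if not lo < hi:
        raise ValueError("invalid age interval")
    hits = [k for k in sorted(available)
            if lo - window_yr <= k * 1000 <= hi + window_yr]
    if hits:
        return hits
    mid = (lo + hi) / 2
    return [min(sorted(available), key=lambda k: (abs(k * 1000 - mid), k))]


def min_occurrence_suitability(model, occurrences: OccurrenceSet,
                               slice0: ClimateGrid) -> float:
    """Minimum predicted suitability over the occurrence points at present.

    The lowest suitability a model assigns to any cell the species actually
    occupies today; hindcast suitability at or above it is evidence the
    fossil site was habitable.
    """
    if len(occurrences) == 0:
        raise ValueError("occurrence set is empty")
    env = extract_env(occurrences.points, slice0)
    return float(np.min(model.predict_suitability(env)))


def suitability_at_fossil(maps: list[SuitabilityMap],
                          fossil: FossilRecord) -> list[float]:
    """Containing-cell suitability at the fossil location, one per map."""
    out = []
    for m in maps:
        try:
            out.append(m.value_at(fossil.lon, fossil.lat))
        except ValueError as exc:
            raise ValueError(
                f"fossil {fossil.fossil_id} at slice {m.age} kyr: {exc}"
            ) from exc
    return out


@dataclass
class CandidateRow:
    """Evidence for one candidate species (one algorithm)."""

    species: str
    algorithm: str
    per_slice_suitability: dict[int, float]
    max_suitability: float          # S: best hindcast suitability at the fossil
    min_current_suitability: float  # m: weakest occupied cell at present
    plausible: bool                 # S >= m
    ratio: float                    # S / m (sentinel when m == 0)
    diagnostics: dict[int, dict] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "species": self.species, "algorithm": self.algorithm,
            "per_slice_suitability": {str(k): v for k, v
                                      in self.per_slice_suitability.items()},
            "S": self.max_suitability, "m": self.min_current_suitability,
            "plausible": self.plausible,
            "ratio": "inf" if np.isinf(self.ratio) else self.ratio,
            "diagnostics": {str(k): v for k, v in self.diagnostics.items()},
        }


@dataclass
class AssignmentReport:
    """Per-candidate suitability evidence, ranking and headline."""

    fossil_id: str
    slices_evaluated: list[int]
    per_candidate: list[CandidateRow]
    ranking: list[str]          # plausible species by S, descending
    headline: str               # species label or "indeterminate"
    tie_tolerance: float

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.per_candidate:
            row = {"species": c.species, "algorithm": c.algorithm,
                   "S": c.max_suitability, "m": c.min_current_suitability,
                   "plausible": c.plausible, "ratio": c.ratio}
            for k, v in c.per_slice_suitability.items():
                row[f"suit_{k}kyr"] = v
            rows.append(row)
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "fossil_id": self.fossil_id,
            "slices_evaluated": self.slices_evaluated,
            "per_candidate": [c.to_dict() for c in self.per_candidate],
            "ranking": self.ranking,
            "headline": self.headline,
            "tie_tolerance": self.tie_tolerance,
        }


def _candidate_row(species_id, model, occurrences, fossil, stack, slices,
                   aggregate, with_diagnostics):
    maps = hindcast(model, stack, slices, species_id=species_id)
    per_slice = dict(zip(slices, suitability_at_fossil(maps, fossil)))
    values = list(per_slice.values())
    S = max(values) if aggregate == "max" else float(np.mean(values))
    m = min_occurrence_suitability(model, occurrences, stack[0])
    if m == 0:
        plausible = S > 0
        ratio = RATIO_SENTINEL
    else:
        plausible = S >= m
        ratio = S / m
    diagnostics = {}
    if with_diagnostics:
        ref_env = _reference_env(model)
        row, col = stack.geometry.cell_of(fossil.lon, fossil.lat)
        if ref_env is not None:
            for k in slices:
                res = mess(ref_env, stack[k])
                diagnostics[k] = {
                    "mess": float(res.mess[row, col]),
                    "most_dissimilar_variable":
                        res.var_names[int(res.mod[row, col])]
                        if res.mod[row, col] >= 0 else None,
                    "clamped": bool(res.clamping_mask[row, col]),
                }
    return CandidateRow(species=species_id, algorithm=model.algorithm,
                        per_slice_suitability=per_slice, max_suitability=S,
                        min_current_suitability=m, plausible=plausible,
                        ratio=ratio, diagnostics=diagnostics)


def _reference_env(model):
    """Reference sample for MESS at the fossil cell.

    The model's full training table (presences plus background or
    pseudo-absences) when available; models rebuilt from a serialized
    document carry only per-variable training ranges, in which case the two
    range endpoints per variable still flag out-of-range (negative-MESS)
    conditions — the caveat that matters for the assignment.
    """
    if model.variable_names_ is None:
        return None
    env = getattr(model, "training_env_", None)
    if env is None:
        env = np.vstack([model.reference_min_, model.reference_max_])
    return pd.DataFrame(env, columns=list(model.variable_names_))


def assign_fossil(candidates, fossil: FossilRecord, stack: ClimateStack,
                  tie_tolerance: float = 0.01, aggregate: str = "max",
                  with_diagnostics: bool = True,
                  window_yr: float = 500.0) -> AssignmentReport:
    """Rank candidate species for a taxonomically ambiguous fossil.

    Parameters
    ----------
    candidates : list of (species_id, fitted model, cleaned OccurrenceSet)
        One entry per competing species; models must share the stack's
        variables. Candidates are evaluated independently — adding one never
        changes another's evidence.
    fossil : FossilRecord
    stack : ClimateStack
        Must contain slice 0 (for the present-day minimum) and the fossil's
        age slices.
    tie_tolerance : float
        If the top two plausible candidates' hindcast suitabilities differ
        by less than this, the headline is "indeterminate".
    aggregate : {"max", "mean"}
        How per-slice suitabilities collapse to the single score S.

    Returns an :class:`AssignmentReport` with per-candidate evidence rows,
    the plausible-candidate ranking, and the headline species (or
    "indeterminate").
    """
    if not candidates:
        raise ValueError("need at least one candidate")
    if aggregate not in ("max", "mean"):
        raise ValueError(f"unknown aggregate {aggregate!r}")
    if 0 not in stack.slices:
        raise KeyError("stack lacks the present-day (0 kyr) slice")
    slices = slices_for_age((fossil.age_min_bp, fossil.age_max_bp),
                            stack.ages, window_yr=window_yr)
    rows = [
        _candidate_row(sid, model, occ, fossil, stack, slices, aggregate,
                       with_diagnostics)
        for sid, model, occ in candidates
    ]
    plausible = [r for r in rows if r.plausible]
    # Stable, input-order-independent ranking: by S descending, species
    # label as the documented tie-break.
    plausible.sort(key=lambda r: (-r.max_suitability, r.species))
    ranking = [r.species for r in plausible]
    if not plausible:
        headline = "indeterminate"
    elif (len(plausible) > 1
          and plausible[0].max_suitability - plausible[1].max_suitability
          < tie_tolerance):
        headline = "indeterminate"
    else:
        headline = plausible[0].species
    return AssignmentReport(fossil_id=fossil.fossil_id,
                            slices_evaluated=slices, per_candidate=rows,
                            ranking=ranking, headline=headline,
                            tie_tolerance=tie_tolerance)


@dataclass
class ValidationVerdict:
    """Outcome of validating one model against a dated fossil."""

    fossil_id: str
    species: str
    passed: bool
    evidence: CandidateRow
    slices_evaluated: list[int]

    def to_dict(self) -> dict:
        return {"fossil_id": self.fossil_id, "species": self.species,
                "passed": self.passed,
                "slices_evaluated": self.slices_evaluated,
                "evidence": self.evidence.to_dict()}


def validate_against_fossil(model, occurrences: OccurrenceSet,
                            fossil: FossilRecord, stack: ClimateStack,
                            aggregate: str = "max",
                            with_diagnostics: bool = True,
                            window_yr: float = 500.0) -> ValidationVerdict:
    """Validate a model (and the paleoclimate layers) against a known fossil.

    The fossil's identity is known (its candidate list is empty); the
    verdict passes when the hindcast suitability at the fossil reaches the
    species' minimum present-day occurrence suitability (S >= m) — i.e. the
    model predicts the fossil's spatial and temporal position. A fail is a
    verdict, not an error.
    """
    if fossil.candidates:
        raise ValueError(
            "validation mode expects a fossil with an empty candidate list"
        )
    slices = slices_for_age((fossil.age_min_bp, fossil.age_max_bp),
                            stack.ages, window_yr=window_yr)
    row = _candidate_row(occurrences.species_id, model, occurrences, fossil,
                         stack, slices, aggregate, with_diagnostics)
    return ValidationVerdict(fossil_id=fossil.fossil_id,
                             species=occurrences.species_id,
                             passed=row.plausible, evidence=row,
                             slices_evaluated=slices)
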