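"""End-to-end pipeline: clean -> select variables -> fit -> evaluate ->
hindcast -> diagnostics -> fossil validation/assignment, with a manifest.

Every stage seed is derived deterministically from the single pipeline seed
via ``numpy.random.SeedSequence``, so rerunning with the same config and
seed reproduces every artifact bit-for-bit; the manifest records resolved
settings and a sha256 checksum per output file.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .assignment import assign_fossil, validate_against_fossil
from .dataprep import clean_occurrences, draw_background, extract_env, select_noncollinear
from .evaluation import cross_validate
from .grids import ClimateGrid, ClimateStack
from .models import ALGORITHMS, MaxentSDM, LogisticSDM, RandomForestSDM, \
    model_to_json, predict_map
from .raster_io import read_climate_stack, read_fossils_csv, \
    read_occurrences_csv, read_range_mask, write_suitability_map

log = logging.getLogger("paleosdm")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Resolved settings of one pipeline run.

    Defaults follow the conventional SDM protocol: 1000 Maxent iterations,
    1000 background points, regularization multiplier 1.0, convergence
    tolerance 1e-5, 500 random-forest trees, 1000 pseudo-absences, 50
    cross-validation repetitions with a 75/25 split, and a pairwise
    |Pearson r| < 0.7 collinearity threshold.
    """

    climate_dir: str = ""
    occurrences_csv: str = ""
    fossils_csv: str = ""
    out_dir: str = "out"
    range_mask: str = ""
    variables: list[str] = field(default_factory=list)  # empty = all in stack
    algorithms: list[str] = field(default_factory=lambda: ["maxent", "glm", "rf"])
    r_threshold: float = 0.7
    maxent_iterations: int = 1000
    maxent_regularization: float = 1.0
    maxent_tol: float = 1e-5
    n_background: int = 1000
    n_pseudoabsence: int = 1000
    rf_trees: int = 500
    n_reps: int = 50
    split_fraction: float = 0.75
    tie_tolerance: float = 0.01
    slice_window_yr: float = 500.0
    aggregate: str = "max"
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        for algo in cfg.algorithms:
            if algo not in ALGORITHMS:
                raise ValueError(
                    f"unknown algorithm {algo!r}; choose from "
                    f"{sorted(ALGORITHMS)}")
        return cfg


def _stage_seed(base: int, *path: int) -> int:
    """Deterministic 31-bit child seed for a pipeline stage."""
    ss = np.random.SeedSequence([base, *path])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def _subset_stack(stack: ClimateStack, names: list[str]) -> ClimateStack:
    slices = {}
    for age, grid in stack.slices.items():
        slices[age] = ClimateGrid(
            geometry=grid.geometry,
            variables={n: grid.variables[n] for n in names},
            nodata_mask=grid.nodata_mask.copy(), age=age)
    return ClimateStack(slices)


def _build_model(algo: str, cfg: PipelineConfig, seed: int):
    if algo == "maxent":
        return MaxentSDM(max_iterations=cfg.maxent_iterations,
                         regularization_multiplier=cfg.maxent_regularization,
                         convergence_tol=cfg.maxent_tol)
    if algo == "glm":
        return LogisticSDM()
    return RandomForestSDM(n_trees=cfg.rf_trees, seed=seed)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full workflow and return the manifest.

    Stages: read climate stack; clean occurrences; select non-collinear
    variables; per species x algorithm fit on the full data (with seeded
    background/pseudo-absence draws), cross-validate, and map present-day
    suitability; then per fossil either validate (known species) or rank
    candidates, per algorithm plus a cross-algorithm consensus. Artifacts
    and a checksummed manifest land under ``config.out_dir``.
    """
    cfg = config
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "read-climate"
    try:
        stack = read_climate_stack(cfg.climate_dir)
        all_occ = read_occurrences_csv(cfg.occurrences_csv)
        fossils = read_fossils_csv(cfg.fossils_csv) if cfg.fossils_csv else []
        mask = read_range_mask(cfg.range_mask) if cfg.range_mask else None

        stage = "select-variables"
        candidates = cfg.variables or stack.var_names
        selected = select_noncollinear(stack[0], candidates, cfg.r_threshold)
        log.info("stage=%s selected=%s", stage, selected)
        stack = _subset_stack(stack, selected)
        slice0 = stack[0]

        stage = "clean-occurrences"
        cleaned = {}
        for sid, occ in sorted(all_occ.items()):
            cleaned[sid] = clean_occurrences(occ, slice0, range_mask=mask)
            log.info("stage=%s species=%s %s", stage, sid,
                     cleaned[sid].audit)

        stage = "fit-evaluate"
        models: dict[tuple[str, str], object] = {}
        evaluations = {}
        for si, (sid, occ) in enumerate(sorted(cleaned.items())):
            presence_env = extract_env(occ.points, slice0)
            for ai, algo in enumerate(cfg.algorithms):
                seed = _stage_seed(cfg.seed, 1, si, ai)
                mode = "background" if algo == "maxent" else "pseudo-absence"
                n_pts = cfg.n_background if algo == "maxent" else cfg.n_pseudoabsence
                bg = draw_background(slice0, n_pts, mode=mode,
                                     occurrences=occ, seed=seed)
                contrast_env = extract_env(bg.points, slice0)
                model = _build_model(algo, cfg, seed)
                Xp, Xc = presence_env.to_numpy(), contrast_env.to_numpy()
                X = np.vstack([Xp, Xc])
                y = np.concatenate([np.ones(len(Xp), int), np.zeros(len(Xc), int)])
                model.fit(pd.DataFrame(X, columns=selected), y)
                models[(sid, algo)] = model
                log.info("stage=fit species=%s algo=%s seed=%d n=%d",
                         sid, algo, seed, len(X))

                ev = cross_validate(model, Xp, Xc, n_reps=cfg.n_reps,
                                    split_fraction=cfg.split_fraction,
                                    seed=_stage_seed(cfg.seed, 2, si, ai))
                evaluations[f"{sid}.{algo}"] = ev.to_dict()
                m0 = float(np.min(model.predict_suitability(Xp)))
                if m0 == 0:
                    log.warning("stage=fit species=%s algo=%s m=0", sid, algo)
                _json_dump(model_to_json(model),
                           out / f"model_{sid}_{algo}.json")
                smap = predict_map(model, slice0, species_id=sid)
                write_suitability_map(smap, out / f"suitability_{sid}_{algo}_0kyr.tif")
        _json_dump(evaluations, out / "evaluation.json")

        stage = "assign"
        reports = {}
        for fossil in fossils:
            per_algo = {}
            if len(fossil.candidates) <= 1:
                sids = fossil.candidates or sorted(cleaned)
                for algo in cfg.algorithms:
                    per_algo[algo] = {
                        sid: validate_against_fossil(
                            models[(sid, algo)], cleaned[sid], fossil, stack,
                            aggregate=cfg.aggregate,
                            window_yr=cfg.slice_window_yr).to_dict()
                        for sid in sids
                    }
                reports[fossil.fossil_id] = {"mode": "validation",
                                             "per_algorithm": per_algo}
            else:
                headlines = []
                for algo in cfg.algorithms:
                    cand = [(sid, models[(sid, algo)], cleaned[sid])
                            for sid in fossil.candidates]
                    rep = assign_fossil(cand, fossil, stack,
                                        tie_tolerance=cfg.tie_tolerance,
                                        aggregate=cfg.aggregate,
                                        window_yr=cfg.slice_window_yr)
                    per_algo[algo] = rep.to_dict()
                    headlines.append(rep.headline)
                consensus = max(set(headlines), key=headlines.count)
                reports[fossil.fossil_id] = {
                    "mode": "assignment", "per_algorithm": per_algo,
                    "consensus": {
                        "headline": consensus,
                        "n_algorithms_agreeing": headlines.count(consensus),
                        "n_algorithms": len(headlines)},
                }
            log.info("stage=%s fossil=%s", stage, fossil.fossil_id)
        _json_dump(reports, out / "assignment.json")

        stage = "manifest"
        resolved = asdict(cfg)
        artifacts = sorted(p for p in out.iterdir()
                           if p.is_file() and p.name != "manifest.json")
        manifest = {
            "software": {"name": "paleosdm", "version": __version__},
            "config": resolved,
            "selected_variables": selected,
            "species": {sid: occ.audit for sid, occ in cleaned.items()},
            "checksums": {p.name: _sha256(p) for p in artifacts},
        }
        _json_dump(manifest, out / "manifest.json")
        return manifest
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc
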