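"""Occurrence cleaning, variable selection and background construction.

These are the standard preprocessing steps of presence-background niche
modelling: deduplicate records to grid-cell resolution, drop points off the
valid climate surface or outside a known range polygon, eliminate collinear
bioclimatic variables (pairwise |Pearson r| below a threshold, 0.7 by
convention), and draw random background or pseudo-absence points.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from shapely.geometry import Point
from shapely.prepared import prep

from .grids import BackgroundSet, ClimateGrid, GridGeometry, OccurrenceSet

__all__ = [
    "clean_occurrences",
    "select_noncollinear",
    "draw_background",
    "extract_env",
]


def clean_occurrences(raw: OccurrenceSet, grid: ClimateGrid,
                      range_mask=None) -> OccurrenceSet:
    """Clean a raw occurrence table against a climate grid.

    Applies, in order: drop points off-grid or on nodata cells; drop points
    outside ``range_mask`` (a shapely polygon) when given; deduplicate to
    one record per grid cell, keeping the first in input order. Counts
    dropped per rule are recorded in the result's ``audit`` and echoed in
    ``provenance``.

    Raises ``ValueError`` if no point survives (the model would be
    unfittable).
    """
    geom = grid.geometry
    pts = raw.points
    n0 = len(pts)
    rows, cols = geom.cells_of(pts)
    on_grid = geom.contains(rows, cols)
    valid = on_grid.copy()
    valid[on_grid] &= ~grid.nodata_mask[rows[on_grid], cols[on_grid]]
    n_nodata = int(n0 - valid.sum())

    n_masked = 0
    if range_mask is not None:
        prepared = prep(range_mask)
        inside = np.array([
            valid[i] and prepared.intersects(Point(pts[i, 0], pts[i, 1]))
            for i in range(n0)
        ])
        n_masked = int(valid.sum() - inside.sum())
        valid = inside

    keep = np.zeros(n0, dtype=bool)
    seen: set[tuple[int, int]] = set()
    for i in np.nonzero(valid)[0]:
        cell = (int(rows[i]), int(cols[i]))
        if cell not in seen:
            seen.add(cell)
            keep[i] = True
    n_dup = int(valid.sum() - keep.sum())

    if not keep.any():
        raise ValueError(
            f"no occurrence of {raw.species_id!r} survived cleaning "
            f"({n0} in: {n_nodata} off-grid/nodata, {n_masked} outside range, "
            f"{n_dup} duplicate cells)"
        )
    audit = {"input": n0, "dropped_nodata": n_nodata,
             "dropped_outside_range": n_masked, "dropped_duplicate_cell": n_dup,
             "kept": int(keep.sum())}
    prov = (f"{raw.provenance}; " if raw.provenance else "") + (
        f"cleaned: kept {audit['kept']}/{n0} "
        f"(nodata {n_nodata}, range {n_masked}, dup {n_dup})"
    )
    return OccurrenceSet(species_id=raw.species_id, points=pts[keep],
                         provenance=prov, audit=audit)


def select_noncollinear(grid: ClimateGrid, candidate_vars: list[str],
                        threshold: float = 0.7) -> list[str]:
    """Greedy elimination of collinear variables over valid cells.

    While any surviving pair has ``|Pearson r| >= threshold``, the member of
    the worst (most correlated) pair with the larger mean absolute
    correlation to all remaining variables is dropped; ties keep the
    earlier-listed variable. Constant variables have undefined correlation
    and are dropped first with a warning. Survivors are returned in input
    order and are pairwise below the threshold.
    """
    if len(candidate_vars) < 2:
        raise ValueError("need at least two candidate variables")
    if not (0 < threshold <= 1):
        raise ValueError("threshold must lie in (0, 1]")
    missing = [v for v in candidate_vars if v not in grid.variables]
    if missing:
        raise KeyError(f"variables not on grid: {missing}")

    vm = grid.valid_mask
    data = {v: grid.variables[v][vm] for v in candidate_vars}
    alive = []
    for v in candidate_vars:
        if np.std(data[v]) == 0:
            warnings.warn(
                f"variable {v!r} is constant over valid cells; dropped "
                "(undefined correlation)", stacklevel=2)
        else:
            alive.append(v)

    def corr(a: str, b: str) -> float:
        return float(np.corrcoef(data[a], data[b])[0, 1])

    while len(alive) > 1:
        worst, pair = 0.0, None
        for i in range(len(alive)):
            for j in range(i + 1, len(alive)):
                r = abs(corr(alive[i], alive[j]))
                if r > worst:
                    worst, pair = r, (alive[i], alive[j])
        if worst < threshold or pair is None:
            break
        a, b = pair
        mean_abs = {
            v: np.mean([abs(corr(v, o)) for o in alive if o != v])
            for v in (a, b)
        }
        # Drop the more globally correlated member; ties keep the one
        # listed earlier in the input.
        drop = b if mean_abs[b] >= mean_abs[a] else a
        alive.remove(drop)
    return alive


def draw_background(grid: ClimateGrid, n: int, mode: str = "background",
                    occurrences: OccurrenceSet | None = None,
                    seed: int = 0) -> BackgroundSet:
    """Draw random background or pseudo-absence cells.

    ``n`` cells are drawn uniformly at random without replacement from the
    grid's valid cells; in pseudo-absence mode the species' occupied cells
    are excluded first (pseudo-absences must not overlap occurrences).
    Points are reported at cell centres.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    geom = grid.geometry
    eligible = grid.valid_mask.copy()
    excluded = None
    if mode == "pseudo-absence":
        if occurrences is None:
            raise ValueError("pseudo-absence mode requires occurrences")
        rows, cols = geom.cells_of(occurrences.points)
        inside = geom.contains(rows, cols)
        eligible[rows[inside], cols[inside]] = False
        excluded = occurrences.species_id
    elif mode != "background":
        raise ValueError(f"unknown mode {mode!r}")

    idx = np.nonzero(eligible.ravel())[0]
    if n > idx.size:
        raise ValueError(
            f"requested {n} {mode} points but only {idx.size} eligible cells"
        )
    rng = np.random.Generator(np.random.PCG64(seed))
    chosen = rng.choice(idx, size=n, replace=False)
    rows, cols = np.unravel_index(chosen, geom.shape)
    lon, lat = geom.cell_center(rows, cols)
    return BackgroundSet(points=np.column_stack([lon, lat]), mode=mode,
                         excluded_species=excluded)


def extract_env(points: np.ndarray, grid: ClimateGrid) -> pd.DataFrame:
    """Environment values at each point's containing cell.

    Returns one row per point with columns in the grid's variable order.
    Points off-grid or on nodata cells raise an error naming the point.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    geom = grid.geometry
    rows, cols = geom.cells_of(pts)
    inside = geom.contains(rows, cols)
    if not inside.all():
        i = int(np.nonzero(~inside)[0][0])
        raise ValueError(f"point ({pts[i, 0]}, {pts[i, 1]}) is off-grid")
    bad = grid.nodata_mask[rows, cols]
    if bad.any():
        i = int(np.nonzero(bad)[0][0])
        raise ValueError(
            f"point ({pts[i, 0]}, {pts[i, 1]}) falls on a nodata cell"
        )
    return grid.env_table(rows, cols)
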