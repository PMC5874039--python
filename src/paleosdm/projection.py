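"""Hindcasting and non-analogue climate diagnostics (clamping, MESS, MoD).

Transferring a model fitted on present-day climate to millennial paleoclimate
slices risks extrapolation beyond the training environment. Two standard
safeguards are provided: *clamping* (truncating projection-time values to
the training range, applied inside the prediction path by default) and the
*multivariate environmental similarity surface* (MESS), whose negative
values mark cells where at least one variable falls outside the reference
range, together with the *most dissimilar variable* (MoD) map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import ClimateGrid, ClimateStack, SuitabilityMap
from .models import predict_map

__all__ = ["hindcast", "mess", "clamp", "MessResult"]


def hindcast(model, stack: ClimateStack, ages: list[int], species_id: str = "",
             clamp: bool | None = None) -> list[SuitabilityMap]:
    """Project a fitted model onto selected slices of a climate stack.

    Returns one suitability map per requested age, in the order given.
    ``clamp=None`` uses the model's own default (on), so
    ``hindcast(model, stack, [0])`` is bit-identical to
    ``predict_map(model, stack[0])``.
    """
    missing = [a for a in ages if a not in stack.slices]
    if missing:
        raise KeyError(
            f"ages {missing} not in stack (available: {stack.ages})"
        )
    return [predict_map(model, stack[a], species_id=species_id, clamp=clamp)
            for a in ages]


@dataclass
class MessResult:
    """MESS similarity, most-dissimilar-variable index and clamping mask."""

    mess: np.ndarray            # similarity per cell (NaN on nodata)
    mod: np.ndarray             # int index of the most dissimilar variable (-1 nodata)
    clamping_mask: np.ndarray   # True where any variable is outside reference
    reference_ranges: dict[str, tuple[float, float]]
    var_names: list[str]


def _similarity(ref: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Piecewise MESS similarity of values ``v`` against a reference sample.

    With ``f`` the percentage of reference values strictly below ``v``:
    ``(v-min)/(max-min)*100`` if f = 0; ``2f`` if f <= 50; ``2(100-f)`` if
    f < 100; ``(max-v)/(max-min)*100`` if f = 100. A constant reference
    yields -inf (with a warning) for values outside it.
    """
    ref = np.sort(np.asarray(ref, dtype=float))
    n = ref.size
    lo, hi = ref[0], ref[-1]
    f = np.searchsorted(ref, v, side="left") / n * 100.0
    span = hi - lo
    if span == 0:
        out = np.where(v == lo, 100.0, -np.inf)
        if np.any(v != lo):
            warnings.warn(
                "constant reference variable with projected values outside "
                "it: similarity set to -inf", stacklevel=3)
        return out
    out = np.empty_like(np.asarray(v, dtype=float))
    below = f == 0
    above = f == 100
    lower = (f > 0) & (f <= 50)
    upper = (f > 50) & (f < 100)
    out[below] = (np.asarray(v)[below] - lo) / span * 100.0
    out[lower] = 2 * f[lower]
    out[upper] = 2 * (100.0 - f[upper])
    out[above] = (hi - np.asarray(v)[above]) / span * 100.0
    return out


def mess(reference_env: pd.DataFrame, grid: ClimateGrid) -> MessResult:
    """Multivariate environmental similarity of a grid to a reference sample.

    Per cell, each variable's similarity is computed against the reference
    column; MESS is the minimum across variables and MoD its argmin (lowest
    variable index on ties). MESS is negative exactly where some variable
    lies outside the reference range; the clamping mask marks those cells.
    """
    if len(reference_env) == 0:
        raise ValueError("reference environment is empty")
    names = [v for v in grid.var_names if v in reference_env.columns]
    if set(names) != set(reference_env.columns):
        raise KeyError(
            "grid variables do not match reference columns: "
            f"grid {grid.var_names}, reference {list(reference_env.columns)}"
        )
    vm = grid.valid_mask
    sims = np.empty((len(names),) + grid.geometry.shape)
    ranges = {}
    out_of_range = np.zeros(grid.geometry.shape, dtype=bool)
    for j, name in enumerate(names):
        ref = reference_env[name].to_numpy(dtype=float)
        ranges[name] = (float(ref.min()), float(ref.max()))
        vals = grid.variables[name]
        sims[j] = _similarity(ref, vals)
        out_of_range |= (vals < ranges[name][0]) | (vals > ranges[name][1])
    mess_grid = sims.min(axis=0)
    mod_grid = sims.argmin(axis=0).astype(int)
    mess_grid = np.where(vm, mess_grid, np.nan)
    mod_grid = np.where(vm, mod_grid, -1)
    clamping_mask = out_of_range & vm
    return MessResult(mess=mess_grid, mod=mod_grid, clamping_mask=clamping_mask,
                      reference_ranges=ranges, var_names=names)


def clamp(grid: ClimateGrid,
          reference_ranges: dict[str, tuple[float, float]]
          ) -> tuple[ClimateGrid, np.ndarray]:
    """Truncate a grid's variables to reference ranges.

    Returns a new grid with values below/above each variable's reference
    min/max replaced by that bound, plus a boolean mask of cells where any
    variable changed. Nodata status is untouched.
    """
    missing = [v for v in grid.var_names if v not in reference_ranges]
    if missing:
        raise KeyError(f"no reference range for variable(s): {missing}")
    changed = np.zeros(grid.geometry.shape, dtype=bool)
    new_vars = {}
    for name in grid.var_names:
        lo, hi = reference_ranges[name]
        vals = grid.variables[name]
        clipped = np.clip(vals, lo, hi)
        changed |= (clipped != vals) & grid.valid_mask
        new_vars[name] = clipped
    out = ClimateGrid(geometry=grid.geometry, variables=new_vars,
                      nodata_mask=grid.nodata_mask.copy(), age=grid.age)
    return out, changed
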