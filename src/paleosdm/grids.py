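"""Core raster containers shared by every stage of the pipeline.

Coordinates are WGS84 decimal degrees in lon/lat order. Grids follow the
usual raster convention: the origin is the north-west corner, rows increase
southward, columns eastward, and a point belongs to the cell whose half-open
interval contains it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GridGeometry",
    "ClimateGrid",
    "ClimateStack",
    "OccurrenceSet",
    "BackgroundSet",
    "SuitabilityMap",
]


@dataclass(frozen=True)
class GridGeometry:
    """Geotransform of a regular lon/lat grid.

    Parameters
    ----------
    west, north : float
        Coordinates of the outer (north-west) corner of cell (0, 0), degrees.
    cell_size : float
        Square cell edge in decimal degrees.
    nrows, ncols : int
        Grid shape.
    """

    west: float
    north: float
    cell_size: float
    nrows: int
    ncols: int

    def __post_init__(self) -> None:
        if self.nrows < 1 or self.ncols < 1:
            raise ValueError("grid dimensions must be positive")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    def cell_of(self, lon: float, lat: float) -> tuple[int, int]:
        """Row/col of the cell containing a point (half-open intervals)."""
        col = int(np.floor((lon - self.west) / self.cell_size))
        row = int(np.floor((self.north - lat) / self.cell_size))
        return row, col

    def cells_of(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        pts = np.asarray(points, dtype=float)
        cols = np.floor((pts[:, 0] - self.west) / self.cell_size).astype(int)
        rows = np.floor((self.north - pts[:, 1]) / self.cell_size).astype(int)
        return rows, cols

    def contains(self, row: np.ndarray, col: np.ndarray) -> np.ndarray:
        return (row >= 0) & (row < self.nrows) & (col >= 0) & (col < self.ncols)

    def cell_center(self, row: np.ndarray, col: np.ndarray):
        lon = self.west + (np.asarray(col) + 0.5) * self.cell_size
        lat = self.north - (np.asarray(row) + 0.5) * self.cell_size
        return lon, lat

    def center_lonlat(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrid of all cell-center coordinates, shape (nrows, ncols)."""
        rows, cols = np.meshgrid(
            np.arange(self.nrows), np.arange(self.ncols), indexing="ij"
        )
        return self.cell_center(rows, cols)


@dataclass
class ClimateGrid:
    """One time slice: a set of co-registered climate variable rasters.

    ``variables`` maps variable name -> 2-D float array (order is
    meaningful and preserved). ``nodata_mask`` is True where cells carry no
    data; all variables share it.
    """

    geometry: GridGeometry
    variables: dict[str, np.ndarray]
    nodata_mask: np.ndarray
    age: int = 0

    def __post_init__(self) -> None:
        if not self.variables:
            raise ValueError("ClimateGrid needs at least one variable")
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.nodata_mask.shape != self.geometry.shape:
            raise ValueError("nodata_mask shape does not match geometry")
        for name, arr in self.variables.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != self.geometry.shape:
                raise ValueError(f"variable {name!r} shape does not match geometry")
            self.variables[name] = arr

    @property
    def var_names(self) -> list[str]:
        return list(self.variables)

    @property
    def valid_mask(self) -> np.ndarray:
        return ~self.nodata_mask

    def n_valid(self) -> int:
        return int(self.valid_mask.sum())

    def env_table(self, rows: np.ndarray, cols: np.ndarray) -> pd.DataFrame:
        """Environment values at given cells, one row per cell."""
        data = {name: arr[rows, cols] for name, arr in self.variables.items()}
        return pd.DataFrame(data)

    def valid_env_table(self) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
        """Environment at every valid cell plus the cell indices."""
        rows, cols = np.nonzero(self.valid_mask)
        return self.env_table(rows, cols), rows, cols


@dataclass
class ClimateStack:
    """Time-indexed stack of :class:`ClimateGrid` sharing one geometry.

    Keys of ``slices`` are ages in integer kyr BP (0 = present).
    """

    slices: dict[int, ClimateGrid]

    def __post_init__(self) -> None:
        if not self.slices:
            raise ValueError("empty climate stack")
        self.slices = dict(sorted(self.slices.items()))
        ref = next(iter(self.slices.values()))
        for age, grid in self.slices.items():
            if grid.geometry != ref.geometry:
                raise ValueError(f"slice {age} geometry differs from the stack's")
            if grid.var_names != ref.var_names:
                raise ValueError(f"slice {age} variables differ from the stack's")

    @property
    def ages(self) -> list[int]:
        return list(self.slices)

    @property
    def geometry(self) -> GridGeometry:
        return next(iter(self.slices.values())).geometry

    @property
    def var_names(self) -> list[str]:
        return next(iter(self.slices.values())).var_names

    def __getitem__(self, age: int) -> ClimateGrid:
        try:
            return self.slices[age]
        except KeyError:
            raise KeyError(
                f"age {age} kyr not in stack (available: {self.ages})"
            ) from None


@dataclass
class OccurrenceSet:
    """Cleaned or raw presence points for one species."""

    species_id: str
    points: np.ndarray  # (n, 2) lon/lat
    provenance: str = ""
    audit: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class BackgroundSet:
    """Background or pseudo-absence points."""

    points: np.ndarray  # (n, 2) lon/lat
    mode: str = "background"  # "background" | "pseudo-absence"
    excluded_species: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("background", "pseudo-absence"):
            raise ValueError(f"unknown background mode {self.mode!r}")
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class SuitabilityMap:
    """Predicted suitability surface in [0, 1] on a climate grid's geometry.

    ``values`` holds NaN on nodata cells.
    """

    geometry: GridGeometry
    values: np.ndarray
    age: int
    species_id: str = ""
    algorithm: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.geometry.shape:
            raise ValueError("values shape does not match geometry")

    @property
    def valid_mask(self) -> np.ndarray:
        return ~np.isnan(self.values)

    def value_at(self, lon: float, lat: float) -> float:
        """Containing-cell suitability at a point."""
        row, col = self.geometry.cell_of(lon, lat)
        if not (0 <= row < self.geometry.nrows and 0 <= col < self.geometry.ncols):
            raise ValueError(f"point ({lon}, {lat}) is off-grid")
        v = self.values[row, col]
        if np.isnan(v):
            raise ValueError(f"point ({lon}, {lat}) falls on a nodata cell")
        return float(v)
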