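"""File formats: GeoTIFF rasters, occurrence/fossil CSVs, climate stacks.

Rasters are written as single-band GeoTIFF (float64, NaN nodata) with the
standard georeferencing tags (ModelPixelScale, ModelTiepoint, a WGS84
GeoKeyDirectory and GDAL_NODATA), so the files round-trip here and open in
GDAL-based tools. One file per variable per slice, named
``<var>_<age>kyr.tif``.

CSV schemas: occurrences ``species,lon,lat``; fossils
``fossil_id,lon,lat,age_min_bp,age_max_bp,candidates`` with candidates
``|``-separated.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .assignment import FossilRecord
from .grids import ClimateGrid, ClimateStack, GridGeometry, OccurrenceSet, SuitabilityMap

__all__ = [
    "write_geotiff",
    "read_geotiff",
    "write_climate_stack",
    "read_climate_stack",
    "write_suitability_map",
    "read_occurrences_csv",
    "write_occurrences_csv",
    "read_fossils_csv",
    "write_fossils_csv",
]

_FILE_RE = re.compile(r"^(?P<var>.+)_(?P<age>\d+)kyr\.tif$")

# GeoTIFF tag ids
_MODEL_PIXEL_SCALE = 33550
_MODEL_TIEPOINT = 33922
_GEO_KEY_DIRECTORY = 34735
_GDAL_NODATA = 42113

# Minimal WGS84 geographic key directory:
# GTModelType=Geographic(2), GTRasterType=PixelIsArea(1), GeographicType=4326
_WGS84_KEYS = (1, 1, 0, 3,
               1024, 0, 1, 2,
               1025, 0, 1, 1,
               2048, 0, 1, 4326)


def write_geotiff(path, values: np.ndarray, geometry: GridGeometry) -> None:
    """Write one 2-D float raster as a georeferenced TIFF (NaN = nodata)."""
    values = np.asarray(values, dtype=np.float64)
    if values.shape != geometry.shape:
        raise ValueError("values shape does not match geometry")
    extratags = [
        (_MODEL_PIXEL_SCALE, "d", 3,
         (geometry.cell_size, geometry.cell_size, 0.0)),
        (_MODEL_TIEPOINT, "d", 6,
         (0.0, 0.0, 0.0, geometry.west, geometry.north, 0.0)),
        (_GEO_KEY_DIRECTORY, "H", len(_WGS84_KEYS), _WGS84_KEYS),
        (_GDAL_NODATA, "s", 0, "nan"),
    ]
    tifffile.imwrite(str(path), values, extratags=extratags)


def read_geotiff(path) -> tuple[np.ndarray, GridGeometry]:
    """Read a raster written by :func:`write_geotiff` (or equivalent)."""
    with tifffile.TiffFile(str(path)) as tif:
        page = tif.pages[0]
        values = page.asarray().astype(np.float64)
        tags = page.tags
        try:
            scale = tags[_MODEL_PIXEL_SCALE].value
            tiepoint = tags[_MODEL_TIEPOINT].value
        except KeyError:
            raise ValueError(f"{path}: missing GeoTIFF georeferencing tags")
    cell = float(scale[0])
    west, north = float(tiepoint[3]), float(tiepoint[4])
    geom = GridGeometry(west=west, north=north, cell_size=cell,
                        nrows=values.shape[0], ncols=values.shape[1])
    return values, geom


def write_climate_stack(stack: ClimateStack, out_dir) -> list[Path]:
    """Write every slice/variable as ``<var>_<age>kyr.tif`` files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for age, grid in stack.slices.items():
        for name in grid.var_names:
            values = np.where(grid.nodata_mask, np.nan, grid.variables[name])
            path = out_dir / f"{name}_{age}kyr.tif"
            write_geotiff(path, values, grid.geometry)
            written.append(path)
    return written


def read_climate_stack(directory, pattern: str = "*.tif") -> ClimateStack:
    """Assemble a climate stack from ``<var>_<age>kyr.tif`` files.

    All files must share geometry; every age must provide the same variable
    set (a gap is reported file-by-name). Nodata is taken as NaN; variables
    of one slice share the union nodata mask.
    """
    directory = Path(directory)
    files = sorted(directory.glob(pattern))
    parsed = []
    for f in files:
        m = _FILE_RE.match(f.name)
        if m:
            parsed.append((m.group("var"), int(m.group("age")), f))
    if not parsed:
        raise FileNotFoundError(
            f"no files matching '<var>_<age>kyr.tif' under {directory}"
        )
    ages = sorted({age for _, age, _ in parsed})
    var_names = sorted({var for var, _, _ in parsed})
    missing = [f"{var}_{age}kyr.tif" for age in ages for var in var_names
               if not any(v == var and a == age for v, a, _ in parsed)]
    if missing:
        raise FileNotFoundError(f"incomplete stack; missing: {missing}")

    geom = None
    slices = {}
    for age in ages:
        variables = {}
        nodata = None
        for var in var_names:
            path = next(f for v, a, f in parsed if v == var and a == age)
            values, g = read_geotiff(path)
            if geom is None:
                geom = g
            elif g != geom:
                raise ValueError(f"{path.name}: geometry differs from stack's")
            bad = np.isnan(values)
            nodata = bad if nodata is None else (nodata | bad)
            variables[var] = values
        for var in var_names:
            variables[var] = np.where(nodata, np.nan, variables[var])
        slices[age] = ClimateGrid(geometry=geom, variables=variables,
                                  nodata_mask=nodata, age=age)
    return ClimateStack(slices)


def write_suitability_map(smap: SuitabilityMap, path) -> None:
    write_geotiff(path, smap.values, smap.geometry)


def read_range_mask(path):
    """Read a range polygon from a GeoJSON or WKT file (shapely geometry)."""
    import json

    from shapely import from_wkt
    from shapely.geometry import shape

    text = Path(path).read_text().strip()
    if text.startswith("{"):
        doc = json.loads(text)
        if doc.get("type") == "FeatureCollection":
            from shapely.ops import unary_union
            return unary_union([shape(f["geometry"]) for f in doc["features"]])
        if doc.get("type") == "Feature":
            return shape(doc["geometry"])
        return shape(doc)
    return from_wkt(text)


def read_occurrences_csv(path) -> dict[str, OccurrenceSet]:
    """Read a ``species,lon,lat`` CSV into per-species occurrence sets."""
    df = pd.read_csv(path)
    required = {"species", "lon", "lat"}
    if not required.issubset(df.columns):
        raise ValueError(f"occurrence CSV needs columns {sorted(required)}")
    out = {}
    for sid, sub in df.groupby("species", sort=True):
        out[str(sid)] = OccurrenceSet(
            species_id=str(sid),
            points=sub[["lon", "lat"]].to_numpy(dtype=float),
            provenance=str(path))
    return out


def write_occurrences_csv(occurrences, path) -> None:
    """Write occurrence sets (iterable or single) to a ``species,lon,lat`` CSV."""
    if isinstance(occurrences, OccurrenceSet):
        occurrences = [occurrences]
    rows = []
    for occ in occurrences:
        for lon, lat in occ.points:
            rows.append({"species": occ.species_id, "lon": lon, "lat": lat})
    pd.DataFrame(rows, columns=["species", "lon", "lat"]).to_csv(path, index=False)


def read_fossils_csv(path) -> list[FossilRecord]:
    df = pd.read_csv(path)
    required = {"fossil_id", "lon", "lat", "age_min_bp", "age_max_bp"}
    if not required.issubset(df.columns):
        raise ValueError(f"fossil CSV needs columns {sorted(required)}")
    fossils = []
    for _, row in df.iterrows():
        cand = row.get("candidates", "")
        if pd.isna(cand):
            cand = ""
        candidates = [c for c in str(cand).split("|") if c]
        fossils.append(FossilRecord(
            fossil_id=str(row["fossil_id"]), lon=float(row["lon"]),
            lat=float(row["lat"]), age_min_bp=float(row["age_min_bp"]),
            age_max_bp=float(row["age_max_bp"]), candidates=candidates))
    return fossils


def write_fossils_csv(fossils: list[FossilRecord], path) -> None:
    rows = [{
        "fossil_id": f.fossil_id, "lon": f.lon, "lat": f.lat,
        "age_min_bp": f.age_min_bp, "age_max_bp": f.age_max_bp,
        "candidates": "|".join(f.candidates),
    } for f in fossils]
    pd.DataFrame(rows, columns=["fossil_id", "lon", "lat", "age_min_bp",
                                "age_max_bp", "candidates"]
                 ).to_csv(path, index=False)
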