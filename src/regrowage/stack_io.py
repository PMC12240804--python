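"""Raster/vector data model and I/O for annual land-cover class stacks.

The annual change product is modelled as a stack of single-band GeoTIFFs,
one per year, each pixel holding a condensed land-cover class code.  A small
code table maps raw raster integers to the condensed vocabulary so real
products with richer sub-classes can be adapted purely through configuration.

GeoTIFFs are read and written with :mod:`tifffile`.  Georeferencing (an
affine transform plus a CRS identifier) is carried in the standard GeoTIFF
ModelPixelScale / ModelTiepoint tags and, authoritatively, in a JSON
ImageDescription; the nodata value uses the GDAL_NODATA ASCII tag.
"""

from __future__ import annotations

import enum
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import tifffile

logger = logging.getLogger("regrowage")

# GeoTIFF / GDAL tag codes
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


class ClassCode(enum.IntEnum):
    """Condensed land-cover class vocabulary.

    NODATA is an observation gap, never a land-cover state.
    """

    NODATA = 0
    UNDISTURBED = 1
    DEGRADED = 2
    NONFOREST = 3
    REGROWTH = 4
    PLANTATION = 5
    WATER = 6


#: Default raw-value -> ClassCode table (identity on the condensed codes).
DEFAULT_CODE_TABLE: dict[int, ClassCode] = {int(c): c for c in ClassCode}


@dataclass(frozen=True)
class GeoRef:
    """Affine georeferencing: ``x = c + a*col + b*row``, ``y = f + d*col + e*row``.

    ``transform`` is the 6-tuple ``(a, b, c, d, e, f)``; ``crs`` is an
    identifier string (e.g. ``"EPSG:3857"`` or ``"synthetic"``).
    """

    transform: tuple[float, float, float, float, float, float]
    crs: str = "synthetic"

    def pixel_center(self, row, col):
        a, b, c, d, e, f = self.transform
        x = c + a * (np.asarray(col) + 0.5) + b * (np.asarray(row) + 0.5)
        y = f + d * (np.asarray(col) + 0.5) + e * (np.asarray(row) + 0.5)
        return x, y

    @property
    def pixel_width(self) -> float:
        return abs(self.transform[0])

    @property
    def pixel_height(self) -> float:
        return abs(self.transform[4])


def pixel_area_from_georef(georef: GeoRef) -> float:
    """Pixel area in hectares implied by a projected (metre-unit) transform."""
    return georef.pixel_width * georef.pixel_height / 10_000.0


@dataclass
class AnnualClassStack:
    """Per-pixel class codes for a consecutive run of years."""

    years: np.ndarray  # (n_years,) int, consecutive ascending
    grid: np.ndarray  # (n_years, rows, cols) uint8 of ClassCode values
    georef: GeoRef
    pixel_area: float  # hectares per pixel

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        if self.grid.ndim != 3 or self.grid.shape[0] != self.years.size:
            raise ValueError("grid must be (n_years, rows, cols) matching years")
        if self.years.size and not np.all(np.diff(self.years) == 1):
            raise ValueError("years must be consecutive ascending")
        if self.pixel_area <= 0:
            raise ValueError("pixel_area must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape[1:]

    def layer(self, year: int) -> np.ndarray:
        idx = int(year) - int(self.years[0])
        if idx < 0 or idx >= self.years.size:
            raise KeyError(f"year {year} not in stack ({self.years[0]}-{self.years[-1]})")
        return self.grid[idx]


@dataclass
class AgeMap:
    """Regenerating-forest age for a target year; 0 = not regenerating."""

    target_year: int
    ages: np.ndarray  # (rows, cols) integer
    georef: GeoRef
    pixel_area: float

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages)
        if self.ages.ndim != 2:
            raise ValueError("ages must be 2-D")
        if self.pixel_area <= 0:
            raise ValueError("pixel_area must be positive")


@dataclass
class MaskRaster:
    """Boolean mask sharing shape and georef with the stack it masks."""

    data: np.ndarray
    georef: GeoRef

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)


# ---------------------------------------------------------------------------
# Low-level GeoTIFF helpers
# ---------------------------------------------------------------------------

def write_raster(path, array: np.ndarray, georef: GeoRef, nodata=None) -> None:
    """Write a single-band GeoTIFF with georeferencing tags."""
    a, b, c, d, e, f = georef.transform
    desc = json.dumps(
        {"transform": [a, b, c, d, e, f], "crs": georef.crs,
         "nodata": None if nodata is None else float(nodata)}
    )
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (abs(a), abs(e), 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, c, f, 0.0)),
    ]
    if nodata is not None:
        extratags.append((_TAG_GDAL_NODATA, "s", 0, str(nodata)))
    tifffile.imwrite(path, np.asarray(array), description=desc, extratags=extratags)


def read_raster(path):
    """Read a single-band GeoTIFF -> (array, GeoRef, nodata-or-None)."""
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        array = page.asarray()
        desc = page.tags.get("ImageDescription")
        transform = None
        crs = "unknown"
        nodata = None
        if desc is not None:
            try:
                meta = json.loads(desc.value)
                transform = tuple(meta["transform"])
                crs = meta.get("crs", crs)
                nodata = meta.get("nodata")
            except (ValueError, KeyError, TypeError):
                pass
        if transform is None:
            # fall back to standard geo tags (north-up only)
            scale = page.tags.get(_TAG_MODEL_PIXEL_SCALE)
            tie = page.tags.get(_TAG_MODEL_TIEPOINT)
            if scale is not None and tie is not None:
                sx, sy = scale.value[0], scale.value[1]
                x0, y0 = tie.value[3], tie.value[4]
                transform = (sx, 0.0, x0, 0.0, -sy, y0)
            else:
                transform = (1.0, 0.0, 0.0, 0.0, -1.0, 0.0)
        nd_tag = page.tags.get(_TAG_GDAL_NODATA)
        if nodata is None and nd_tag is not None:
            nodata = float(nd_tag.value)
    return array, GeoRef(tuple(float(v) for v in transform), crs), nodata


# ---------------------------------------------------------------------------
# Stack reading
# ---------------------------------------------------------------------------

_YEAR_RE = re.compile(r"(19|20)\d{2}")


def _year_from_path(path) -> int:
    m = None
    for m in _YEAR_RE.finditer(Path(path).stem):
        pass
    if m is None:
        raise ValueError(f"cannot infer year from filename {path!r}")
    return int(m.group(0))


def _apply_code_table(raw: np.ndarray, code_table: Mapping[int, ClassCode]):
    out = np.full(raw.shape, int(ClassCode.NODATA), dtype=np.uint8)
    known = np.zeros(raw.shape, dtype=bool)
    for raw_value, code in code_table.items():
        hit = raw == raw_value
        out[hit] = int(code)
        known |= hit
    return out, int((~known).sum())


def read_class_stack(
    paths: Sequence,
    year_range: tuple[int, int] | None = None,
    code_table: Mapping[int, ClassCode] | None = None,
    pixel_area: float | None = None,
) -> AnnualClassStack:
    """Assemble per-year single-band GeoTIFFs into an :class:`AnnualClassStack`.

    Years are inferred from the file names (last 4-digit year in the stem);
    the file list may be given in any order.  Raster values absent from the
    code table are mapped to NODATA with a logged warning count.
    """
    code_table = dict(DEFAULT_CODE_TABLE if code_table is None else code_table)
    by_year: dict[int, Path] = {}
    for p in paths:
        y = _year_from_path(p)
        if y in by_year:
            raise ValueError(f"duplicate file for year {y}")
        by_year[y] = Path(p)
    years = sorted(by_year)
    if year_range is not None:
        lo, hi = year_range
        for y in range(lo, hi + 1):
            if y not in by_year:
                raise ValueError(f"missing year {y}")
        years = list(range(lo, hi + 1))
    else:
        for y in range(years[0], years[-1] + 1):
            if y not in by_year:
                raise ValueError(f"missing year {y}")

    layers = []
    georef = None
    unknown_total = 0
    for y in years:
        raw, g, _ = read_raster(by_year[y])
        if georef is None:
            georef = g
            shape = raw.shape
        else:
            if raw.shape != shape:
                raise ValueError(
                    f"grid shape mismatch for year {y}: {raw.shape} vs {shape}")
            if g.transform != georef.transform:
                raise ValueError(
                    f"georef mismatch for year {y}: {g.transform} vs {georef.transform}")
        coded, n_unknown = _apply_code_table(np.asarray(raw), code_table)
        unknown_total += n_unknown
        layers.append(coded)
    if unknown_total:
        logger.warning("read_class_stack: %d pixel-values not in code table mapped to NODATA",
                       unknown_total)
    if pixel_area is None:
        pixel_area = pixel_area_from_georef(georef)
    stack = AnnualClassStack(np.array(years), np.stack(layers), georef, pixel_area)
    stack.unknown_value_count = unknown_total
    return stack


def read_class_stack_multiband(path, first_year: int, **kwargs) -> AnnualClassStack:
    """Convenience reader for a single multiband file (band i = year first_year+i)."""
    with tifffile.TiffFile(path) as tif:
        arr = tif.asarray()
    if arr.ndim == 2:
        arr = arr[None]
    _, georef, _ = read_raster(path)
    code_table = dict(kwargs.get("code_table") or DEFAULT_CODE_TABLE)
    coded, n_unknown = _apply_code_table(arr, code_table)
    if n_unknown:
        logger.warning("multiband read: %d unknown values mapped to NODATA", n_unknown)
    years = np.arange(first_year, first_year + arr.shape[0])
    pixel_area = kwargs.get("pixel_area") or pixel_area_from_georef(georef)
    return AnnualClassStack(years, coded, georef, pixel_area)


def write_class_stack(stack: AnnualClassStack, directory, prefix: str = "classes") -> list[Path]:
    """Write one GeoTIFF per year; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, y in enumerate(stack.years):
        p = directory / f"{prefix}_{int(y)}.tif"
        write_raster(p, stack.grid[i], stack.georef)
        paths.append(p)
    return paths


# ---------------------------------------------------------------------------
# Age map I/O
# ---------------------------------------------------------------------------

def write_age_map(age_map: AgeMap, path) -> None:
    """Write an age map as an int16 GeoTIFF with 0 encoded as nodata."""
    write_raster(path, age_map.ages.astype(np.int16), age_map.georef, nodata=0)


def read_age_map(path, target_year: int | None = None, pixel_area: float | None = None) -> AgeMap:
    arr, georef, nodata = read_raster(path)
    ages = np.asarray(arr, dtype=np.int16)
    if nodata is not None and nodata != 0:
        ages = np.where(ages == nodata, 0, ages)
    if pixel_area is None:
        pixel_area = pixel_area_from_georef(georef)
    return AgeMap(target_year if target_year is not None else -1, ages, georef, pixel_area)


def write_mask(mask: MaskRaster, path) -> None:
    write_raster(path, mask.data.astype(np.uint8), mask.georef)


def read_mask(path) -> MaskRaster:
    arr, georef, _ = read_raster(path)
    return MaskRaster(arr != 0, georef)


# ---------------------------------------------------------------------------
# Alignment validation
# ---------------------------------------------------------------------------

@dataclass
class AlignmentEntry:
    name: str
    shape_ok: bool
    transform_ok: bool
    crs_ok: bool
    detail: str = ""

    @property
    def ok(self) -> bool:
        return self.shape_ok and self.transform_ok and self.crs_ok


def validate_alignment(stack: AnnualClassStack, rasters: Mapping[str, tuple]) -> list[AlignmentEntry]:
    """Report-only check that each raster shares the stack's shape/transform/CRS.

    ``rasters`` maps a name to ``(array, GeoRef)`` or to an object exposing
    ``.data``/``.ages`` and ``.georef``.
    """
    report = []
    for name, item in rasters.items():
        if isinstance(item, tuple):
            arr, georef = item
        else:
            arr = getattr(item, "data", None)
            if arr is None:
                arr = item.ages
            georef = item.georef
        shape_ok = np.asarray(arr).shape == stack.shape
        transform_ok = tuple(georef.transform) == tuple(stack.georef.transform)
        crs_ok = georef.crs == stack.georef.crs
        detail = ""
        if not transform_ok:
            dx = georef.transform[2] - stack.georef.transform[2]
            dy = georef.transform[5] - stack.georef.transform[5]
            detail = f"origin offset ({dx}, {dy}); {georef.transform} vs {stack.georef.transform}"
        report.append(AlignmentEntry(name, shape_ok, transform_ok, crs_ok, detail))
    return report


# ---------------------------------------------------------------------------
# GeoJSON helpers (country polygons)
# ---------------------------------------------------------------------------

def write_geojson(features: Iterable[dict], path) -> None:
    fc = {"type": "FeatureCollection", "features": list(features)}
    Path(path).write_text(json.dumps(fc))


def read_geojson(path) -> list[dict]:
    fc = json.loads(Path(path).read_text())
    if fc.get("type") != "FeatureCollection":
        raise ValueError("expected a GeoJSON FeatureCollection")
    return fc["features"]
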