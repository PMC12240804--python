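"""Coarse-grid aggregation of age maps and percentile hotspot classification.

Age maps are aggregated to square cells (default 30 km) anchored at the
raster's top-left corner in the raster's own CRS.  Hotspot tiers mark cells
whose old-regenerating-forest area is at or above the 75th / 90th percentile
of cells with nonzero old area (linear-interpolation percentiles; ties at
the threshold are included).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stack_io import AgeMap

logger = logging.getLogger("regrowage")


@dataclass(frozen=True)
class HotspotParams:
    old_threshold: int = 20          # years; "old" regenerating forest
    percentiles: tuple = (75, 90)    # strictly increasing, in (0, 100)
    include_zero_cells: bool = False  # include old_area == 0 cells in percentiles

    def __post_init__(self) -> None:
        ps = self.percentiles
        if not all(0 < p < 100 for p in ps) or list(ps) != sorted(set(ps)):
            raise ValueError("percentiles must be strictly increasing in (0, 100)")


def aggregate_grid(
    age_map: AgeMap,
    cell_size: float = 30_000.0,
    params: HotspotParams = HotspotParams(),
) -> pd.DataFrame:
    """Aggregate an age map to square cells of ``cell_size`` map units.

    Returns a table with one row per cell: ``cell_id, cell_row, cell_col,
    centroid_x, centroid_y, n_regen, mean_age, regen_area, old_area,
    partial, hotspot_tier``.  mean_age is the unweighted mean over
    regenerating pixels and is NaN for cells without any.
    """
    ages = age_map.ages
    rows, cols = ages.shape
    px = age_map.georef.pixel_width
    k = cell_size / px
    k_int = int(round(k))
    if k_int < 1 or abs(k - k_int) > 1e-9:
        raise ValueError(
            f"cell_size {cell_size} is not a positive multiple of pixel edge {px}")
    n_cr = -(-rows // k_int)  # ceil
    n_cc = -(-cols // k_int)

    cell_row = np.arange(rows) // k_int
    cell_col = np.arange(cols) // k_int
    cell_idx = (cell_row[:, None] * n_cc + cell_col[None, :]).ravel()
    flat = ages.ravel()
    regen = flat > 0
    old = flat >= params.old_threshold

    n_cells = n_cr * n_cc
    n_regen = np.bincount(cell_idx[regen], minlength=n_cells)
    age_sum = np.bincount(cell_idx[regen], weights=flat[regen].astype(float),
                          minlength=n_cells)
    n_old = np.bincount(cell_idx[old], minlength=n_cells)

    with np.errstate(invalid="ignore"):
        mean_age = np.where(n_regen > 0, age_sum / np.maximum(n_regen, 1), np.nan)

    ids = np.arange(n_cells)
    cr, cc = ids // n_cc, ids % n_cc
    # centroids of the nominal (full) cells in map coordinates
    a, b, c, d, e, f = age_map.georef.transform
    cx = c + a * (cc + 0.5) * k_int
    cy = f + e * (cr + 0.5) * k_int
    partial = ((cr == n_cr - 1) & (rows % k_int != 0)) | ((cc == n_cc - 1) & (cols % k_int != 0))

    grid = pd.DataFrame(
        {
            "cell_id": ids,
            "cell_row": cr,
            "cell_col": cc,
            "centroid_x": cx,
            "centroid_y": cy,
            "n_regen": n_regen,
            "mean_age": mean_age,
            "regen_area": n_regen * age_map.pixel_area,
            "old_area": n_old * age_map.pixel_area,
            "partial": partial,
            "hotspot_tier": "none",
        }
    )
    if not regen.any():
        logger.warning("aggregate_grid: empty age map (no regenerating pixels)")
    return classify_hotspots(grid, params)


def classify_hotspots(grid: pd.DataFrame, params: HotspotParams = HotspotParams()) -> pd.DataFrame:
    """Assign hotspot tiers by percentile of per-cell old-forest area.

    The thresholds are the stated percentiles of ``old_area`` over cells with
    ``old_area > 0`` (or all cells if ``include_zero_cells``); a cell is in
    the highest tier whose threshold its old_area meets (>=).  Higher-tier
    cell sets nest inside lower ones by construction.
    """
    grid = grid.copy()
    vals = grid["old_area"].to_numpy(dtype=float)
    pool = vals if params.include_zero_cells else vals[vals > 0]
    grid["hotspot_tier"] = "none"
    if pool.size == 0:
        logger.warning("classify_hotspots: no cell with old_area > 0; all tiers 'none'")
        return grid
    for p in params.percentiles:  # ascending: later (higher) tiers overwrite
        thr = np.percentile(pool, p)  # linear interpolation between order stats
        grid.loc[(vals >= thr) & (vals > 0), "hotspot_tier"] = f"p{int(p)}"
    return grid


def grid_to_geojson(grid: pd.DataFrame, cell_size: float, georef) -> list[dict]:
    """GeoJSON square features for the grid cells (for mapping/debugging)."""
    a, b, c, d, e, f = georef.transform
    feats = []
    kx = cell_size / abs(a)
    for rec in grid.itertuples():
        x0 = c + a * rec.cell_col * kx
        y0 = f + e * rec.cell_row * kx
        x1 = x0 + a * kx
        y1 = y0 + e * kx
        ring = [[x0, y0], [x1, y0], [x1, y1], [x0, y1], [x0, y0]]
        feats.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [ring]},
                "properties": {
                    "cell_id": int(rec.cell_id),
                    "mean_age": None if np.isnan(rec.mean_age) else float(rec.mean_age),
                    "regen_area": float(rec.regen_area),
                    "old_area": float(rec.old_area),
                    "hotspot_tier": rec.hotspot_tier,
                },
            }
        )
    return feats
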