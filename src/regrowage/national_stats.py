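"""Country/region zonal statistics, share ratios, age distributions, carbon.

The central container is a *long* country-age table with columns
``country, region, age, area_ha`` (one row per country x age year).  From it
derive per-country and per-region summaries, the old-vs-all share-ratio
statistic, binned age distributions with a deforestation-timing companion
curve, and a fixed-horizon carbon projection for young regenerating forest.

Conventions (matching the analysis this package reproduces): "old" means
age >= 20 years, "young" means age <= 5 years; shares are reported to the
nearest integer percent, share ratios to one decimal; the +/- on mean ages
is a standard deviation and medians are unweighted over pixels with the
lower median taken on ties.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stack_io import AgeMap, AnnualClassStack, ClassCode

logger = logging.getLogger("regrowage")

OLD_THRESHOLD = 20
YOUNG_THRESHOLD = 5
#: Default age-class bins (inclusive edges), partitioning 3..34
DEFAULT_BINS: tuple[tuple[int, int], ...] = (
    (3, 5), (6, 10), (11, 15), (16, 20), (21, 25), (26, 30), (31, 34),
)
MGC_PER_GTC = 1e9


# ---------------------------------------------------------------------------
# Tabulation
# ---------------------------------------------------------------------------

def tabulate_by_country(
    age_map: AgeMap,
    country_raster: np.ndarray,
    region_lookup: dict | None = None,
    country_names: dict | None = None,
) -> pd.DataFrame:
    """Long table of regenerating area by (country, region, age year).

    ``country_raster`` holds integer country ids aligned with the age map;
    ids < 0 (or pixels not matching any id) are tallied under ``"unassigned"``.
    ``region_lookup`` maps country id (or name) -> region label.
    """
    ages = age_map.ages
    if country_raster.shape != ages.shape:
        raise ValueError("country raster not aligned with age map")
    regen = ages > 0
    cid = np.where(country_raster < 0, -1, country_raster)[regen].astype(np.int64)
    a = ages[regen].astype(np.int64)
    n_unassigned = int((cid < 0).sum())
    if n_unassigned:
        logger.info("tabulate_by_country: %d regenerating pixels outside all countries",
                    n_unassigned)
    max_age = int(a.max()) if a.size else 0
    key = (cid + 1) * (max_age + 1) + a  # cid -1 -> slot 0
    counts = np.bincount(key, minlength=(int(cid.max()) + 2 if cid.size else 1) * (max_age + 1))
    rows = []
    n_countries = counts.size // (max_age + 1)
    for slot in range(n_countries):
        for age in range(1, max_age + 1):
            n = counts[slot * (max_age + 1) + age]
            if n == 0:
                continue
            country_id = slot - 1
            name = ("unassigned" if country_id < 0 else
                    (country_names or {}).get(country_id, f"C{country_id:03d}"))
            region = (region_lookup or {}).get(country_id,
                                               (region_lookup or {}).get(name, "all"))
            rows.append((name, region, age, n * age_map.pixel_area))
    table = pd.DataFrame(rows, columns=["country", "region", "age", "area_ha"])
    return table.sort_values(["country", "age"], ignore_index=True)


def country_summary(
    table: pd.DataFrame,
    old_threshold: int = OLD_THRESHOLD,
    young_threshold: int = YOUNG_THRESHOLD,
) -> pd.DataFrame:
    """Per-country totals, old/young areas and age moments from the long table."""
    recs = []
    for country, sub in table.groupby("country", sort=True):
        area = sub["area_ha"].to_numpy(float)
        age = sub["age"].to_numpy(float)
        total = area.sum()
        mean = float((age * area).sum() / total) if total > 0 else np.nan
        var = float((area * (age - mean) ** 2).sum() / total) if total > 0 else np.nan
        recs.append(
            {
                "country": country,
                "region": sub["region"].iloc[0],
                "total_area": total,
                "old_area": area[age >= old_threshold].sum(),
                "young_area": area[age <= young_threshold].sum(),
                "mean_age": mean,
                "sd_age": np.sqrt(var),
                "median_age": _weighted_lower_median(age, area),
            }
        )
    return pd.DataFrame(recs)


def _weighted_lower_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Lower median over pixels (weights are pixel counts x equal pixel area)."""
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cw = np.cumsum(w)
    if cw[-1] <= 0:
        return np.nan
    return float(v[np.searchsorted(cw, cw[-1] / 2.0, side="left")])


# ---------------------------------------------------------------------------
# Share ratio (old-forest share vs all-age share)
# ---------------------------------------------------------------------------

def share_ratio(summary: pd.DataFrame, min_all_share: float = 0.0) -> pd.DataFrame:
    """Per-country ratio of old-forest share to all-age share.

    ``summary`` needs columns ``country, total_area, old_area`` (as produced
    by :func:`country_summary`, or fed directly with published totals).
    A ratio of 1 means a country holds the same share of pan-tropical old
    regenerating forest as of regenerating forest of any age.
    """
    total_all = float(summary["total_area"].sum())
    total_old = float(summary["old_area"].sum())
    if total_old <= 0:
        raise ValueError("pan-tropical old-forest area is zero; ratio undefined")
    out = summary.loc[summary["total_area"] > 0, ["country"]].copy()
    sub = summary.loc[summary["total_area"] > 0]
    out["old_share"] = sub["old_area"].to_numpy(float) / total_old
    out["all_share"] = sub["total_area"].to_numpy(float) / total_all
    out["ratio"] = out["old_share"] / out["all_share"]
    if min_all_share > 0:
        out = out[out["all_share"] >= min_all_share]
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Regional summary
# ---------------------------------------------------------------------------

def regional_summary(
    table: pd.DataFrame,
    old_threshold: int = OLD_THRESHOLD,
    young_threshold: int = YOUNG_THRESHOLD,
) -> pd.DataFrame:
    """Per-region totals, old/young areas and rounded percent shares.

    Accepts either the long (country, region, age, area_ha) table or a
    pre-aggregated table with ``region, total_area, old_area`` columns
    (e.g. published regional areas); shares are region / pan-tropical,
    rounded to the nearest integer percent.
    """
    if {"age", "area_ha"}.issubset(table.columns):
        recs = []
        for region, sub in table.groupby("region", sort=True):
            area = sub["area_ha"].to_numpy(float)
            age = sub["age"].to_numpy(float)
            total = area.sum()
            mean = float((age * area).sum() / total) if total > 0 else np.nan
            var = float((area * (age - mean) ** 2).sum() / total) if total > 0 else np.nan
            recs.append(
                {
                    "region": region,
                    "total_area": total,
                    "old_area": area[age >= old_threshold].sum(),
                    "young_area": area[age <= young_threshold].sum(),
                    "mean_age": mean,
                    "sd_age": np.sqrt(var),
                    "median_age": _weighted_lower_median(age, area),
                }
            )
        reg = pd.DataFrame(recs)
    else:
        reg = table.copy()
    tot_all = float(reg["total_area"].sum())
    tot_old = float(reg["old_area"].sum())
    reg["all_share_pct"] = np.rint(100.0 * reg["total_area"] / tot_all).astype(int)
    reg["old_share_pct"] = (np.rint(100.0 * reg["old_area"] / tot_old).astype(int)
                            if tot_old > 0 else 0)
    if "young_area" in reg.columns:
        tot_young = float(reg["young_area"].sum())
        reg["young_share_pct"] = (np.rint(100.0 * reg["young_area"] / tot_young).astype(int)
                                  if tot_young > 0 else 0)
    return reg


# ---------------------------------------------------------------------------
# Age distribution + deforestation-timing curve
# ---------------------------------------------------------------------------

def age_distribution(
    table: pd.DataFrame,
    stack: AnnualClassStack | None = None,
    region_raster: np.ndarray | None = None,
    region_names: dict | None = None,
    bins: tuple = DEFAULT_BINS,
    target_year: int | None = None,
) -> pd.DataFrame:
    """Binned regenerating area per region, plus deforestation-timing curve.

    Bins are inclusive (lo, hi) pairs partitioning the attainable age range.
    The timing curve counts, per region, transition events into NONFOREST
    from a non-NONFOREST land-cover class, buckets them by lookback
    (target_year - event year) into the same bins and normalises to sum to 1.
    """
    _check_bins(bins)
    rows = []
    for region, sub in table.groupby("region", sort=True):
        for lo, hi in bins:
            m = (sub["age"] >= lo) & (sub["age"] <= hi)
            rows.append((region, f"{lo}-{hi}", lo, hi, float(sub.loc[m, "area_ha"].sum())))
    dist = pd.DataFrame(rows, columns=["region", "bin", "age_lo", "age_hi", "area_ha"])

    if stack is not None:
        ty = int(target_year if target_year is not None else stack.years[-1])
        timing = _deforestation_timing(stack, region_raster, region_names, bins, ty)
        dist = dist.merge(timing, on=["region", "bin"], how="left")
        dist["defor_proportion"] = dist["defor_proportion"].fillna(0.0)
    return dist


def _deforestation_timing(stack, region_raster, region_names, bins, target_year):
    N, ND = int(ClassCode.NONFOREST), int(ClassCode.NODATA)
    if region_raster is None:
        region_raster = np.zeros(stack.shape, dtype=np.int64)
        region_names = {0: "all"}
    counts: dict[tuple, int] = {}
    i1 = int(target_year - stack.years[0])
    for t in range(1, i1 + 1):
        prev, cur = stack.grid[t - 1], stack.grid[t]
        event = (cur == N) & (prev != N) & (prev != ND)
        if not event.any():
            continue
        lookback = target_year - int(stack.years[t])
        for rid in np.unique(region_raster[event]):
            key = (int(rid), lookback)
            counts[key] = counts.get(key, 0) + int((region_raster[event] == rid).sum())
    rows = []
    names = region_names or {}
    rids = sorted({rid for rid, _ in counts})
    for rid in rids:
        per_bin = []
        for lo, hi in bins:
            n = sum(v for (r, lb), v in counts.items() if r == rid and lo <= lb <= hi)
            per_bin.append(n)
        total = sum(per_bin)
        for (lo, hi), n in zip(bins, per_bin):
            rows.append((names.get(rid, f"R{rid}"), f"{lo}-{hi}",
                         n / total if total else 0.0))
    return pd.DataFrame(rows, columns=["region", "bin", "defor_proportion"])


def _check_bins(bins) -> None:
    edges = sorted(bins)
    for i, (lo, hi) in enumerate(edges):
        if hi < lo:
            raise ValueError(f"bin {lo}-{hi} inverted")
        if i and lo <= edges[i - 1][1]:
            raise ValueError("bins overlap")


# ---------------------------------------------------------------------------
# Carbon projection
# ---------------------------------------------------------------------------

@dataclass
class CarbonEstimate:
    total_gtc: float
    horizon_years: int
    young_age_max: int
    area_ha: float
    by_country: pd.DataFrame | None = None


def project_carbon(
    age_map: AgeMap,
    rate_raster: np.ndarray,
    horizon: int = 25,
    young_age_max: int = YOUNG_THRESHOLD,
    min_age: int = 3,
    country_raster: np.ndarray | None = None,
    country_names: dict | None = None,
) -> CarbonEstimate:
    """Potential above-ground carbon from protecting young regenerating forest.

    total = sum over pixels with min_age <= age <= young_age_max of
    rate (MgC/ha/yr) x pixel_area (ha) x horizon (yr), in GtC.
    """
    ages = age_map.ages
    if rate_raster.shape != ages.shape:
        raise ValueError("rate raster not aligned with age map")
    if np.any(rate_raster < 0):
        raise ValueError("carbon accumulation rates must be non-negative")
    qual = (ages >= min_age) & (ages <= young_age_max)
    mgc = rate_raster[qual].astype(float).sum() * age_map.pixel_area * horizon
    by_country = None
    if country_raster is not None:
        if country_raster.shape != ages.shape:
            raise ValueError("country raster not aligned with age map")
        recs = []
        for cid in np.unique(country_raster[qual]):
            m = qual & (country_raster == cid)
            c_mgc = rate_raster[m].astype(float).sum() * age_map.pixel_area * horizon
            name = (country_names or {}).get(int(cid), f"C{int(cid):03d}")
            recs.append({"country": name, "area_ha": float(m.sum() * age_map.pixel_area),
                         "carbon_gtc": c_mgc / MGC_PER_GTC})
        by_country = pd.DataFrame(recs)
    return CarbonEstimate(
        total_gtc=mgc / MGC_PER_GTC,
        horizon_years=horizon,
        young_age_max=young_age_max,
        area_ha=float(qual.sum() * age_map.pixel_area),
        by_country=by_country,
    )
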