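"""Synthetic tropical-landscape generator.

Produces annual class stacks, plantation masks, country polygons, predictor
rasters and carbon-accumulation-rate rasters with the statistical structure
the downstream analysis assumes, so the whole pipeline runs at desk scale
without external data.

The land-cover simulator is a per-pixel Markov chain with one piece of
memory: a NONFOREST pixel may start regrowing only after at least three
consecutive NONFOREST years, so the regrowth-designation rule discriminates
between eligible and ineligible pixels.  Spatial structure comes from
multiplying the base transition probabilities by spatially autocorrelated
log-normal modifier fields (white noise convolved with a Gaussian kernel).
Predictor rasters are smoothed random fields scaled to their ranges; the
ones flagged as causal multiply the re-clearance hazard through a monotone
(log-linear) link, which is what ties predictor values to realised forest
age — older regenerating forest where re-clearance pressure is low.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats
from scipy.ndimage import gaussian_filter
from shapely import geometry as sgeom
from shapely.ops import voronoi_diagram

from .stack_io import AnnualClassStack, ClassCode, GeoRef, MaskRaster


@dataclass(frozen=True)
class PredictorSpec:
    """A synthetic predictor raster and its (possibly null) causal link.

    ``effect`` is the log-linear coefficient on the re-clearance hazard per
    standard deviation of the field: negative effects make regenerating
    forest persist longer (older) where the predictor is high.
    """

    name: str
    low: float = 0.0
    high: float = 1.0
    effect: float = 0.0
    smooth_px: float | None = None  # override config smoothing length


#: Default reduced predictor set (8 of the study's 32), with the causal
#: structure the analysis expects: older forest at high elevation, high
#: forest-landscape integrity and low surrounding forest loss.
DEFAULT_PREDICTORS: tuple[PredictorSpec, ...] = (
    PredictorSpec("elevation", 0.0, 3000.0, effect=-0.5),
    PredictorSpec("flii", 0.0, 10.0, effect=-0.4),
    PredictorSpec("forest_loss", 0.0, 1.0, effect=0.5),
    PredictorSpec("temperature_seasonality", 0.0, 100.0, effect=0.0),
    PredictorSpec("annual_precipitation", 1000.0, 4000.0, effect=0.0),
    PredictorSpec("cropland_extent", 0.0, 1.0, effect=0.0),
    PredictorSpec("gdp", 0.0, 50_000.0, effect=0.0),
    PredictorSpec("soil_organic_carbon", 0.0, 200.0, effect=0.0),
)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic landscape."""

    shape: tuple[int, int] = (96, 96)
    year_range: tuple[int, int] = (1990, 2023)
    pixel_size_m: float = 30.0
    pixel_area: float = 0.09  # hectares (30 m pixel)
    # annual transition probabilities
    p_deforest: float = 0.02          # UNDISTURBED -> NONFOREST
    p_degrade: float = 0.01           # UNDISTURBED -> DEGRADED
    p_degraded_deforest: float = 0.05  # DEGRADED -> NONFOREST
    p_abandon: float = 0.15           # NONFOREST -> REGROWTH (after the gate)
    p_reclear: float = 0.12           # REGROWTH -> NONFOREST (base hazard)
    p_plantation: float = 0.002       # NONFOREST -> PLANTATION
    water_frac: float = 0.01
    min_nonforest_gate: int = 3       # years of NONFOREST before regrowth can start
    # spatial-field parameters
    smooth_px: float = 5.0            # Gaussian kernel length scale, pixels
    hazard_sigma: float = 0.5         # sd of log-normal hazard modifiers
    # predictors and their causal links to the re-clearance hazard
    predictors: tuple[PredictorSpec, ...] = DEFAULT_PREDICTORS
    # carbon accumulation rates (MgC / ha / yr)
    carbon_mean: float = 4.6
    carbon_rel_spread: float = 0.25
    n_countries: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_deforest", "p_degrade", "p_degraded_deforest",
                     "p_abandon", "p_reclear", "p_plantation", "water_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} not in [0, 1]")
        if self.shape[0] <= 0 or self.shape[1] <= 0:
            raise ValueError("grid must have positive area")
        if self.n_countries < 1:
            raise ValueError("n_countries must be >= 1")

    @property
    def georef(self) -> GeoRef:
        s = self.pixel_size_m
        return GeoRef((s, 0.0, 0.0, 0.0, -s, self.shape[0] * s), "synthetic")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.year_range[0], self.year_range[1] + 1)


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=config.seed,
                                                        spawn_key=(stream,)))


def _smooth_field(rng: np.random.Generator, shape, smooth_px: float) -> np.ndarray:
    """Standardised spatially autocorrelated Gaussian field."""
    z = gaussian_filter(rng.standard_normal(shape), sigma=smooth_px, mode="reflect")
    sd = z.std()
    return (z - z.mean()) / (sd if sd > 0 else 1.0)


# ---------------------------------------------------------------------------
# Predictors
# ---------------------------------------------------------------------------

def simulate_predictors(config: SimConfig):
    """Named predictor rasters plus the true-effect record.

    Returns ``(predictors, effects)`` where ``predictors`` maps name to a
    float raster scaled to its [low, high] range and ``effects`` maps name
    to its planted log-hazard coefficient (0 for null predictors).
    """
    rng = _rng(config, 1)
    predictors: dict[str, np.ndarray] = {}
    effects: dict[str, float] = {}
    for spec in config.predictors:
        z = _smooth_field(rng, config.shape, spec.smooth_px or config.smooth_px)
        predictors[spec.name] = spec.low + (spec.high - spec.low) * stats.norm.cdf(z)
        effects[spec.name] = spec.effect
    return predictors, effects


def _reclearance_field(config: SimConfig, predictors, effects) -> np.ndarray:
    """Per-pixel re-clearance probability from base hazard x causal links."""
    log_mult = np.zeros(config.shape)
    for name, eff in effects.items():
        if eff == 0.0:
            continue
        v = predictors[name]
        sd = v.std()
        log_mult += eff * (v - v.mean()) / (sd if sd > 0 else 1.0)
    if config.hazard_sigma > 0:
        log_mult += config.hazard_sigma * _smooth_field(_rng(config, 4), config.shape,
                                                        config.smooth_px)
    return np.clip(config.p_reclear * np.exp(log_mult), 0.0, 1.0)


# ---------------------------------------------------------------------------
# Land-cover simulation
# ---------------------------------------------------------------------------

def simulate_stack(config: SimConfig, predictors=None, effects=None):
    """Per-pixel Markov simulation of the annual class stack.

    Returns ``(stack, plantation_mask)``.  Deterministic for a given config
    (the seed fixes every stream).  Regrowth can only follow a completed
    NONFOREST gap of at least ``min_nonforest_gate`` years, and plantation
    conversion is absorbing.
    """
    if predictors is None or effects is None:
        predictors, effects = simulate_predictors(config)
    rng = _rng(config, 0)
    shape = config.shape
    U, D, N, R = (int(ClassCode.UNDISTURBED), int(ClassCode.DEGRADED),
                  int(ClassCode.NONFOREST), int(ClassCode.REGROWTH))
    P, W = int(ClassCode.PLANTATION), int(ClassCode.WATER)

    reclear = _reclearance_field(config, predictors, effects)
    if config.hazard_sigma > 0:
        defor = np.clip(config.p_deforest *
                        np.exp(config.hazard_sigma *
                               _smooth_field(_rng(config, 5), shape, config.smooth_px)),
                        0.0, 1.0)
    else:
        defor = np.full(shape, config.p_deforest)

    state = np.full(shape, U, dtype=np.uint8)
    if config.water_frac > 0:
        water = _rng(config, 6).random(shape) < config.water_frac
        state[water] = W

    years = config.years
    grid = np.empty((years.size,) + shape, dtype=np.uint8)
    grid[0] = state
    nf_run = np.zeros(shape, dtype=np.int16)
    for t in range(1, years.size):
        u = rng.random(shape)
        new = state.copy()
        is_u, is_d = state == U, state == D
        is_n, is_r = state == N, state == R
        new[is_u & (u < defor)] = N
        new[is_u & (u >= defor) & (u < defor + config.p_degrade)] = D
        new[is_d & (u < config.p_degraded_deforest)] = N
        new[is_n & (u < config.p_plantation)] = P
        eligible = is_n & (nf_run >= config.min_nonforest_gate)
        new[eligible & (u >= config.p_plantation) &
            (u < config.p_plantation + config.p_abandon)] = R
        new[is_r & (u < reclear)] = N
        nf_run = np.where(new == N, nf_run + 1, 0).astype(np.int16)
        state = new
        grid[t] = state
    mask = MaskRaster(grid[-1] == P, config.georef)  # plantation is absorbing
    stack = AnnualClassStack(years, grid, config.georef, config.pixel_area)
    return stack, mask


# ---------------------------------------------------------------------------
# Countries
# ---------------------------------------------------------------------------

def make_countries(config: SimConfig):
    """Voronoi partition of the grid into synthetic countries.

    Returns ``(features, country_raster, names)``: GeoJSON polygon features,
    an aligned int raster of country ids, and an id -> name map.  The raster
    assigns each pixel to the nearest seed point, which is exactly the
    Voronoi cell containing its centre.
    """
    rng = _rng(config, 2)
    rows, cols = config.shape
    georef = config.georef
    xmax = cols * config.pixel_size_m
    ymax = rows * config.pixel_size_m
    pts = np.column_stack([rng.uniform(0, xmax, config.n_countries),
                           rng.uniform(0, ymax, config.n_countries)])
    box = sgeom.box(0, 0, xmax, ymax)

    if config.n_countries == 1:
        polys = [box]
    else:
        vd = voronoi_diagram(sgeom.MultiPoint([sgeom.Point(p) for p in pts]),
                             envelope=box)
        cells = [g.intersection(box) for g in vd.geoms]
        polys = [None] * config.n_countries
        for cell in cells:
            for i, p in enumerate(pts):
                if cell.covers(sgeom.Point(p)):
                    polys[i] = cell
                    break

    # raster by nearest seed point (== Voronoi cell of the pixel centre)
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    px, py = georef.pixel_center(rr, cc)
    d2 = (px[..., None] - pts[:, 0]) ** 2 + (py[..., None] - pts[:, 1]) ** 2
    raster = np.argmin(d2, axis=-1).astype(np.int32)

    names = {i: f"C{i:03d}" for i in range(config.n_countries)}
    features = []
    for i, poly in enumerate(polys):
        features.append(
            {
                "type": "Feature",
                "geometry": sgeom.mapping(poly),
                "properties": {"country_id": i, "name": names[i]},
            }
        )
    return features, raster, names


def assign_regions(config: SimConfig, n_regions: int = 3) -> dict[int, str]:
    """Deterministic country-id -> region label map (round-robin)."""
    labels = ["Americas", "Africa", "Asia-Pacific"][:max(1, n_regions)]
    return {i: labels[i % len(labels)] for i in range(config.n_countries)}


# ---------------------------------------------------------------------------
# Carbon rates
# ---------------------------------------------------------------------------

def simulate_carbon_rates(config: SimConfig) -> np.ndarray:
    """Positive smoothed rate raster (MgC/ha/yr) with the configured mean."""
    if config.carbon_rel_spread == 0:
        return np.full(config.shape, config.carbon_mean)
    z = _smooth_field(_rng(config, 3), config.shape, config.smooth_px)
    rate = config.carbon_mean * (1.0 + config.carbon_rel_spread * z)
    return np.clip(rate, 0.01 * config.carbon_mean, None)
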