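"""Synthetic two-scale environments with a known habitat-suitability truth.

This module generates everything the downstream pipeline consumes, so the
whole analysis can be exercised end to end against a known truth model with
no external data:

* a coarse "national" climate stack (bio3, bio9, bio14, bio15, LULC), with a
  south-to-north temperature gradient in bio9;
* a fine "provincial" stack (aspect, elevation, slope, LULC, nightlight,
  distance to road, distance to water) with a rasterised river;
* wintering-occurrence points sampled from the truth suitability surface;
* a land-cover time series governed by a known urban-growth rule, used to
  validate the cellular-automata simulator;
* scenario climate stacks (warming deltas + precipitation scaling); and
* protected-area masks for gap analysis.

Every generator is a pure function of its parameters and a seed.  Smooth
spatial fields are Gaussian-filtered white noise rescaled to a target range:
the simplest controllable form of spatial autocorrelation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.special import expit

from .grid import GridSpec, Raster
from .occurrence import OccurrenceSet

# Land-cover legend (six general classes)
CROPLAND, FOREST, GRASSLAND, WETLAND, IMPERVIOUS, BARE = 1, 2, 3, 4, 5, 6
LULC_CLASSES = (CROPLAND, FOREST, GRASSLAND, WETLAND, IMPERVIOUS, BARE)
LULC_NAMES = {
    CROPLAND: "cropland",
    FOREST: "forest",
    GRASSLAND: "grassland",
    WETLAND: "wetland",
    IMPERVIOUS: "impervious",
    BARE: "bare",
}

MIN_GRID = 20  # smallest grid edge that still supports Gaussian smoothing


# ---------------------------------------------------------------------------
# Truth model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TruthModel:
    """Known logistic suitability truth used to generate occurrences.

    The linear predictor is

        eta = intercept
            + sum_v linear[v] * x_v
            + sum_v quadratic[v] * (x_v - optimum[v])**2
            + sum_v ramp_slope[v] * max(0, x_v - ramp_threshold[v])
            + water_weight * exp(-dist_water / water_decay_distance)
            + lulc_weight * lulc_class_weights[class]

    and suitability = expit(eta), so it always lies in (0, 1).  A negative
    quadratic coefficient with zero linear term makes the marginal response
    unimodal with its maximum exactly at ``optimum[v]``.
    """

    intercept: float = 0.0
    linear: dict = field(default_factory=dict)
    quadratic: dict = field(default_factory=dict)
    optimum: dict = field(default_factory=dict)
    ramp_threshold: dict = field(default_factory=dict)
    ramp_slope: dict = field(default_factory=dict)
    water_decay_distance: float | None = None  # metres
    water_weight: float = 0.0
    lulc_class_weights: dict = field(default_factory=dict)
    lulc_weight: float = 0.0

    @property
    def optimum_bio9(self) -> float | None:
        """Argmax of the bio9 marginal response (quadratic center)."""
        return self.optimum.get("bio9")

    def predictors(self) -> set:
        names = set(self.linear) | set(self.quadratic) | set(self.ramp_threshold)
        if self.water_decay_distance is not None:
            names.add("dist_water")
        if self.lulc_class_weights:
            names.add("lulc")
        return names


def national_truth() -> TruthModel:
    """Default national-scale truth: a 0 degC bio9 optimum, a dry-month
    precipitation ramp starting near 36 mm, and a wetland-favouring
    land-cover term.  bio3 and bio15 are deliberately unused (nuisance
    variables for importance testing)."""
    return TruthModel(
        intercept=-3.5,
        quadratic={"bio9": -0.10},
        optimum={"bio9": 0.0},
        ramp_threshold={"bio14": 36.0},
        ramp_slope={"bio14": 0.10},
        lulc_class_weights={
            CROPLAND: 0.5,
            FOREST: 0.3,
            GRASSLAND: 0.4,
            WETLAND: 1.0,
            IMPERVIOUS: 0.2,
            BARE: 0.0,
        },
        lulc_weight=3.0,
    )


def provincial_truth() -> TruthModel:
    """Default provincial truth: strong distance-to-water decay (2500 m
    scale), wetland-favouring land cover, and a mild slope penalty.  Aspect
    and nightlight are unused nuisance variables."""
    return TruthModel(
        intercept=-2.0,
        linear={"slope": -0.08},
        water_decay_distance=2500.0,
        water_weight=3.5,
        lulc_class_weights={
            CROPLAND: 0.4,
            FOREST: 0.3,
            GRASSLAND: 0.4,
            WETLAND: 1.0,
            IMPERVIOUS: 0.3,
            BARE: 0.0,
        },
        lulc_weight=1.2,
    )


def true_suitability(stack: dict, truth: TruthModel) -> Raster:
    """Evaluate the truth model over a raster stack -> continuous suitability."""
    needed = truth.predictors()
    missing = needed - set(stack)
    if missing:
        raise KeyError(f"stack missing predictors required by truth: {sorted(missing)}")
    any_raster = next(iter(stack.values()))
    eta = np.full(any_raster.grid.shape, truth.intercept, dtype=float)
    for v, c in truth.linear.items():
        eta += c * stack[v].values
    for v, c in truth.quadratic.items():
        eta += c * (stack[v].values - truth.optimum.get(v, 0.0)) ** 2
    for v, thr in truth.ramp_threshold.items():
        eta += truth.ramp_slope[v] * np.clip(stack[v].values - thr, 0.0, None)
    if truth.water_decay_distance is not None:
        eta += truth.water_weight * np.exp(
            -stack["dist_water"].values / truth.water_decay_distance
        )
    if truth.lulc_class_weights:
        w = np.zeros_like(eta)
        for cls, wt in truth.lulc_class_weights.items():
            w[stack["lulc"].values == cls] = wt
        eta += truth.lulc_weight * w
    mask = np.zeros(any_raster.grid.shape, dtype=bool)
    for r in stack.values():
        mask |= r.nodata_mask
    return Raster(any_raster.grid, expit(eta), mask, "continuous")


# ---------------------------------------------------------------------------
# Scenarios
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScenarioSpec:
    """One future climate scenario: an SSP pathway at a time horizon.

    ``temperature_delta`` (degC) is added to bio9; bio14/bio15 are scaled by
    ``precipitation_factor``.  Deltas are stand-ins ordered as the pathways
    are (optimistic <= moderate <= pessimistic within a period)."""

    scenario_id: str
    period: str
    temperature_delta: float
    precipitation_factor: float = 1.0


DEFAULT_SCENARIOS: tuple[ScenarioSpec, ...] = (
    ScenarioSpec("SSP126", "2030s", 0.5, 1.02),
    ScenarioSpec("SSP245", "2030s", 1.0, 1.04),
    ScenarioSpec("SSP585", "2030s", 1.5, 1.06),
    ScenarioSpec("SSP126", "2050s", 0.8, 1.03),
    ScenarioSpec("SSP245", "2050s", 1.5, 1.06),
    ScenarioSpec("SSP585", "2050s", 2.5, 1.10),
)


def make_future_climate(stack: dict, scenario: ScenarioSpec) -> dict:
    """Apply a scenario's warming delta and precipitation scaling to a stack."""
    out = {}
    for name, r in stack.items():
        if name == "bio9":
            out[name] = r.with_values(r.values + scenario.temperature_delta)
        elif name in ("bio14", "bio15"):
            out[name] = r.with_values(r.values * scenario.precipitation_factor)
        else:
            out[name] = r.copy()
    return out


# ---------------------------------------------------------------------------
# Field generators
# ---------------------------------------------------------------------------

def _check_grid(grid: GridSpec) -> None:
    if grid.n_rows < MIN_GRID or grid.n_cols < MIN_GRID:
        raise ValueError(
            f"grid {grid.shape} too small to support smoothing (need >= "
            f"{MIN_GRID}x{MIN_GRID})"
        )


def smooth_field(grid: GridSpec, rng: np.random.Generator, lo: float, hi: float,
                 sigma: float = 4.0) -> np.ndarray:
    """Gaussian-filtered white noise rescaled (min-max) to [lo, hi]."""
    z = ndimage.gaussian_filter(rng.standard_normal(grid.shape), sigma=sigma)
    zmin, zmax = z.min(), z.max()
    if zmax == zmin:  # pathological but possible on tiny grids
        return np.full(grid.shape, 0.5 * (lo + hi))
    return lo + (z - zmin) / (zmax - zmin) * (hi - lo)


def bio9_gradient(grid: GridSpec, south: float = 20.0, north: float = -15.0) -> np.ndarray:
    """The deterministic latitudinal component of bio9: row 0 (north) coldest,
    last row (south) warmest, linear in between."""
    t = np.linspace(0.0, 1.0, grid.n_rows)[:, None]  # 0 at north, 1 at south
    return north + t * (south - north) * np.ones((1, grid.n_cols))


def _categorical_mosaic(grid: GridSpec, rng: np.random.Generator,
                        sigma: float = 3.0) -> np.ndarray:
    """Six-class land-cover mosaic from quantile-binned smooth noise."""
    z = ndimage.gaussian_filter(rng.standard_normal(grid.shape), sigma=sigma)
    qs = np.quantile(z, [1 / 6, 2 / 6, 3 / 6, 4 / 6, 5 / 6])
    return (np.digitize(z, qs) + 1).astype(np.int64)  # codes 1..6


def make_national_environment(grid: GridSpec, seed: int,
                              noise_amplitude: float = 2.0,
                              sigma: float = 4.0) -> dict:
    """Coarse climate + land-cover stack for the national scale.

    bio9 is the latitudinal gradient (roughly [-15, 20] degC) plus smooth
    correlated noise; bio14 spans [0, 100] mm; bio3/bio15 are smooth
    nuisance fields; lulc is a six-class categorical mosaic.
    """
    _check_grid(grid)
    rng = np.random.default_rng(seed)
    bio9 = bio9_gradient(grid) + noise_amplitude * (
        smooth_field(grid, rng, -1.0, 1.0, sigma)
    )
    bio14 = smooth_field(grid, rng, 0.0, 100.0, sigma)
    bio3 = smooth_field(grid, rng, 20.0, 60.0, sigma)
    bio15 = smooth_field(grid, rng, 30.0, 120.0, sigma)
    lulc = _categorical_mosaic(grid, rng)
    return {
        "bio3": Raster(grid, bio3, kind="continuous"),
        "bio9": Raster(grid, bio9, kind="continuous"),
        "bio14": Raster(grid, bio14, kind="continuous"),
        "bio15": Raster(grid, bio15, kind="continuous"),
        "lulc": Raster(grid, lulc, kind="categorical"),
    }


def _river_path(grid: GridSpec, rng: np.random.Generator) -> np.ndarray:
    """Random-walk river crossing the grid west to east; boolean mask."""
    mask = np.zeros(grid.shape, dtype=bool)
    row = grid.n_rows // 2 + int(rng.integers(-grid.n_rows // 6, grid.n_rows // 6 + 1))
    for col in range(grid.n_cols):
        row = int(np.clip(row + rng.integers(-1, 2), 1, grid.n_rows - 2))
        mask[row, col] = True
    return mask


def make_provincial_environment(grid: GridSpec, seed: int,
                                sigma: float = 5.0) -> dict:
    """Fine-scale stack: topography, land cover, human pressure, water.

    Elevation is a smooth field; slope and aspect follow from its finite
    differences; distance-to-water is the Euclidean distance transform of a
    random-walk river (metres); distance-to-road likewise for a straight
    road; nightlight is a sparse smooth field.
    """
    _check_grid(grid)
    rng = np.random.default_rng(seed)
    s = grid.cell_size

    elevation = smooth_field(grid, rng, 300.0, 2000.0, sigma)
    dzdy, dzdx = np.gradient(elevation, s, s)
    slope = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
    aspect = np.degrees(np.arctan2(-dzdx, dzdy)) % 360.0

    lulc = _categorical_mosaic(grid, rng)
    river = _river_path(grid, rng)
    lulc[river] = WETLAND
    dist_water = ndimage.distance_transform_edt(~river) * s

    road_row = grid.n_rows // 3
    road = np.zeros(grid.shape, dtype=bool)
    road[road_row, :] = True
    dist_road = ndimage.distance_transform_edt(~road) * s

    nightlight = np.clip(smooth_field(grid, rng, -40.0, 63.0, sigma / 2), 0.0, 63.0)

    return {
        "aspect": Raster(grid, aspect, kind="continuous"),
        "elevation": Raster(grid, elevation, kind="continuous"),
        "slope": Raster(grid, slope, kind="continuous"),
        "lulc": Raster(grid, lulc, kind="categorical"),
        "nightlight": Raster(grid, nightlight, kind="continuous"),
        "dist_road": Raster(grid, dist_road, kind="continuous"),
        "dist_water": Raster(grid, dist_water, kind="continuous"),
    }


def wedge_study_region(grid: GridSpec, min_width_fraction: float = 0.25) -> np.ndarray:
    """Nodata mask for a study region that narrows toward the north.

    Real study regions are not rectangles; a wedge whose east-west width
    shrinks linearly northward makes the suitable-area latitude profile
    genuinely unimodal (its peak sits at the southern boundary of the
    climatically suitable strip), so warming-induced northward shifts of
    that boundary register as strict peak-latitude increases instead of
    ties across a saturated plateau.  Returns True outside the region.
    """
    mask = np.ones(grid.shape, dtype=bool)
    c0 = grid.n_cols // 2
    for i in range(grid.n_rows):
        w = min_width_fraction + (1.0 - min_width_fraction) * i / (grid.n_rows - 1)
        half = int(round(w * grid.n_cols / 2))
        mask[i, max(0, c0 - half):min(grid.n_cols, c0 + half)] = False
    return mask


def mask_stack(stack: dict, region_nodata: np.ndarray) -> dict:
    """Apply a study-region nodata mask to every layer of a stack."""
    return {
        name: Raster(r.grid, r.values, region_nodata | r.nodata_mask, r.kind)
        for name, r in stack.items()
    }


# ---------------------------------------------------------------------------
# Occurrences
# ---------------------------------------------------------------------------

def sample_occurrences(suitability: Raster, n: int, seed: int) -> OccurrenceSet:
    """Draw ``n`` distinct cells with probability proportional to suitability;
    return one presence point at each sampled cell's center."""
    if n < 1:
        raise ValueError("n must be >= 1")
    p = suitability.values.astype(float).copy()
    p[suitability.nodata_mask] = 0.0
    flat = p.ravel()
    positive = int((flat > 0).sum())
    if n > positive:
        raise ValueError(
            f"n={n} exceeds the {positive} cells with positive suitability"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(flat.size, size=n, replace=False, p=flat / flat.sum())
    rows, cols = np.unravel_index(idx, suitability.grid.shape)
    x, y = suitability.grid.cell_center(rows, cols)
    return OccurrenceSet(points=list(zip(x.tolist(), y.tolist())), label="presence")


# ---------------------------------------------------------------------------
# Land-cover time series with a known growth rule
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UrbanGrowthRule:
    """Known land-cover transition rule: grassland cells within a distance of
    the initial urban core convert to impervious; the conversion radius grows
    linearly each time step."""

    source_class: int = GRASSLAND
    target_class: int = IMPERVIOUS
    base_distance: float = 0.0    # map units at t0
    growth_per_step: float = 0.0  # map units added per step


@dataclass
class LulcSeries:
    maps: dict            # {"t0": Raster, "t1": Raster, "t2": Raster}
    rule: UrbanGrowthRule
    drivers: dict         # driver stack for transition-model fitting
    dist_urban: Raster    # distance (map units) to the t0 urban core


def make_lulc_series(grid: GridSpec, seed: int,
                     rule: UrbanGrowthRule | None = None,
                     core_half_width: int = 3) -> LulcSeries:
    """Three-date land-cover series driven by :class:`UrbanGrowthRule`.

    t0 is a random six-class mosaic with an impervious core block planted at
    the grid center; t1 and t2 apply the deterministic distance rule with
    radii ``base + g`` and ``base + 2 g``.  The returned driver stack
    (distance to the urban core, elevation, white noise) is what the
    transition-suitability model trains on; only the distance drives truth.
    """
    _check_grid(grid)
    rng = np.random.default_rng(seed)
    if rule is None:
        rule = UrbanGrowthRule(
            base_distance=0.0,
            growth_per_step=0.15 * min(grid.n_rows, grid.n_cols) * grid.cell_size,
        )
    t0 = _categorical_mosaic(grid, rng)
    r0, c0 = grid.n_rows // 2, grid.n_cols // 2
    h = core_half_width
    core = np.zeros(grid.shape, dtype=bool)
    core[r0 - h:r0 + h, c0 - h:c0 + h] = True
    t0[core] = rule.target_class

    # the rule measures distance to the planted urban core, not to every
    # impervious cell of the background mosaic
    dist = ndimage.distance_transform_edt(~core) * grid.cell_size

    def apply_rule(steps: int) -> np.ndarray:
        radius = rule.base_distance + steps * rule.growth_per_step
        out = t0.copy()
        out[(t0 == rule.source_class) & (dist <= radius)] = rule.target_class
        return out

    t1, t2 = apply_rule(1), apply_rule(2)
    # current land use is itself a driver (conversion eligibility), as in
    # the usual land-expansion driver rosters
    drivers = {
        "dist_urban": Raster(grid, dist, kind="continuous"),
        "lulc_t0": Raster(grid, t0.astype(float), kind="continuous"),
        "elevation": Raster(grid, smooth_field(grid, rng, 300.0, 2000.0), kind="continuous"),
        "noise": Raster(grid, rng.standard_normal(grid.shape), kind="continuous"),
    }
    maps = {
        "t0": Raster(grid, t0, kind="categorical"),
        "t1": Raster(grid, t1, kind="categorical"),
        "t2": Raster(grid, t2, kind="categorical"),
    }
    return LulcSeries(maps=maps, rule=rule, drivers=drivers,
                      dist_urban=drivers["dist_urban"])


# ---------------------------------------------------------------------------
# Protected areas
# ---------------------------------------------------------------------------

def make_protected_areas(grid: GridSpec, fraction: float, seed: int) -> Raster:
    """Random circular reserves covering ~``fraction`` of cells (within 10 %
    relative).  Blobs are added until the target is reached; the last blob is
    trimmed from its rim inward if it overshoots."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    mask = np.zeros(grid.shape, dtype=bool)
    target = int(round(fraction * grid.n_rows * grid.n_cols))
    if target == 0:
        return Raster(grid, mask.astype(np.int64), kind="binary")
    if fraction >= 1.0:
        return Raster(grid, np.ones(grid.shape, dtype=np.int64), kind="binary")
    rng = np.random.default_rng(seed)
    rr, cc = np.mgrid[0:grid.n_rows, 0:grid.n_cols]
    radius = max(2.0, np.sqrt(0.05 * target / np.pi))
    for _ in range(10000):
        if mask.sum() >= target:
            break
        cy = rng.integers(0, grid.n_rows)
        cx = rng.integers(0, grid.n_cols)
        d2 = (rr - cy) ** 2 + (cc - cx) ** 2
        blob = d2 <= radius ** 2
        new = blob & ~mask
        excess = mask.sum() + new.sum() - target
        if excess > 0:
            # trim the blob from its rim inward to land on the target count
            order = np.argsort(-d2[new].ravel(), kind="stable")
            flat_idx = np.flatnonzero(new.ravel())[order[:excess]]
            new_flat = new.ravel()
            new_flat[flat_idx] = False
            new = new_flat.reshape(grid.shape)
        mask |= new
    return Raster(grid, mask.astype(np.int64), kind="binary")
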