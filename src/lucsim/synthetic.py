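"""Seeded synthetic landscapes, driving factors and statistical series.

The real study area (a province-scale mosaic of cultivated land, forest,
water and growing built-up land) is emulated here by construction: a
spatially autocorrelated categorical landscape, smooth/distance-based
driving-factor surfaces, near-exponential class-area trajectories (so a
first-order grey model is well posed), and paired regional/national
socio-economic series for the valuation correction factors.  Everything is
a pure function of its spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .raster import DEFAULT_LEGEND, CategoricalRaster, FactorStack


@dataclass
class SyntheticScenarioSpec:
    """Parameters of a synthetic study area.

    ``class_fractions`` are target area shares (must sum to 1);
    ``trend_rates`` are per-class annual multiplicative growth rates of the
    class-area series; ``autocorrelation_scale`` is the Gaussian smoothing
    length (in cells) that controls patch size.
    """

    grid_shape: tuple[int, int] = (200, 200)
    n_classes: int = 8
    cell_area_ha: float = 900.0  # one 3 km x 3 km cell
    autocorrelation_scale: float = 6.0
    class_fractions: tuple[float, ...] = (0.28, 0.24, 0.22, 0.06, 0.05, 0.01, 0.11, 0.03)
    trend_rates: tuple[float, ...] = (0.995, 0.996, 1.001, 0.998, 1.003, 0.995, 1.012, 0.97)
    years: tuple[int, ...] = (1995, 2000, 2005, 2010, 2015, 2018)
    seed: int = 0
    legend: dict[int, str] = field(default_factory=lambda: dict(DEFAULT_LEGEND))

    def __post_init__(self) -> None:
        rows, cols = self.grid_shape
        if rows <= 0 or cols <= 0:
            raise ValueError("grid_shape must be positive")
        if len(self.class_fractions) != self.n_classes:
            raise ValueError("class_fractions length must equal n_classes")
        if len(self.trend_rates) != self.n_classes:
            raise ValueError("trend_rates length must equal n_classes")
        if abs(sum(self.class_fractions) - 1.0) > 1e-9:
            raise ValueError("class_fractions must sum to 1")
        if any(f < 0 for f in self.class_fractions):
            raise ValueError("class_fractions must be nonnegative")
        if any(r <= 0 for r in self.trend_rates):
            raise ValueError("trend_rates must be positive")
        if list(self.years) != sorted(set(self.years)):
            raise ValueError("years must be strictly increasing")

    @property
    def codes(self) -> list[int]:
        return list(range(1, self.n_classes + 1))


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], scale: float) -> np.ndarray:
    """Gaussian-smoothed white noise, standardised to zero mean unit sd."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=scale, mode="reflect")
    sd = f.std()
    return (f - f.mean()) / sd if sd > 0 else np.zeros(shape)


def generate_landscape(spec: SyntheticScenarioSpec) -> CategoricalRaster:
    """Generate a spatially autocorrelated class-coded landscape.

    Each class gets an independent smoothed random field; cells take the
    argmax field after per-class offsets are calibrated so realised shares
    match ``spec.class_fractions`` (within ~2 percentage points).  Classes
    with zero target share are excluded outright.
    """
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.grid_shape
    n_cells = rows * cols
    fracs = np.asarray(spec.class_fractions, dtype=float)

    for code, f in zip(spec.codes, fracs):
        if f > 0 and f * n_cells < 1:
            raise ValueError(
                f"grid of {n_cells} cells too small to realize class "
                f"{spec.legend.get(code, code)} (share {f})"
            )

    fields = np.stack([_smooth_field(rng, (rows, cols), spec.autocorrelation_scale)
                       for _ in range(spec.n_classes)])
    offsets = np.zeros(spec.n_classes)
    offsets[fracs == 0] = -np.inf
    # multiplicative-step calibration of offsets toward the target shares
    for _ in range(200):
        labels = np.argmax(fields + offsets[:, None, None], axis=0)
        shares = np.bincount(labels.ravel(), minlength=spec.n_classes) / n_cells
        err = fracs - shares
        if np.all(np.abs(err[fracs > 0]) < 0.005):
            break
        offsets[fracs > 0] += 1.5 * err[fracs > 0]
    grid = (labels + 1).astype(np.int64)
    return CategoricalRaster(grid, spec.cell_area_ha, dict(spec.legend))


#: layer blueprint mirroring the study's 16 driving factors
FACTOR_NAMES_CONTINUOUS = ["gdp", "population_density", "dem",
                           "annual_temperature", "annual_rainfall"]
FACTOR_NAMES_DISTANCE = ["dist_railway", "dist_expressway", "dist_highway",
                         "dist_river", "dist_town", "dist_rural_settlement"]
FACTOR_NAMES_MULTICLASS = ["slope", "soil_sand", "soil_powder", "soil_clay",
                           "soil_erosion"]


def generate_driving_factors(landscape: CategoricalRaster,
                             n_continuous: int = 5,
                             n_distance: int = 6,
                             n_multiclass: int = 5,
                             seed: int = 0) -> FactorStack:
    """Generate a factor stack aligned to ``landscape``.

    Continuous layers are smooth random fields; distance layers are Euclidean
    distances to a few seeded feature cells; multi-class layers are smooth
    fields quantised into small integer codes.  The default 5+6+5 layout
    mirrors the 16 socio-economic / natural / traffic-location factors of
    the study design.
    """
    if min(n_continuous, n_distance, n_multiclass) < 0:
        raise ValueError("layer counts must be nonnegative")
    rng = np.random.default_rng(seed)
    shape = landscape.shape
    layers: list[np.ndarray] = []
    names: list[str] = []
    kinds: list[str] = []

    def take_name(pool: list[str], i: int, stem: str) -> str:
        return pool[i] if i < len(pool) else f"{stem}_{i + 1}"

    for i in range(n_continuous):
        layers.append(_smooth_field(rng, shape, 8.0))
        names.append(take_name(FACTOR_NAMES_CONTINUOUS, i, "continuous"))
        kinds.append("continuous")
    for i in range(n_distance):
        n_feat = int(rng.integers(1, 6))
        mask = np.ones(shape, dtype=bool)
        idx = rng.choice(shape[0] * shape[1], size=n_feat, replace=False)
        mask.ravel()[idx] = False
        layers.append(ndimage.distance_transform_edt(mask).astype(float))
        names.append(take_name(FACTOR_NAMES_DISTANCE, i, "distance"))
        kinds.append("continuous")
    for i in range(n_multiclass):
        f = _smooth_field(rng, shape, 10.0)
        q = np.quantile(f, [0.2, 0.4, 0.6, 0.8])
        layers.append(np.digitize(f, q).astype(float) + 1.0)
        names.append(take_name(FACTOR_NAMES_MULTICLASS, i, "multiclass"))
        kinds.append("multi-class")
    if not layers:
        layers = [np.zeros(shape)]
        return FactorStack(np.stack(layers)[:0], [], [])
    return FactorStack(np.stack(layers), names, kinds)


def generate_area_series(spec: SyntheticScenarioSpec, noise_sd: float = 0.01,
                         total_area: float | None = None) -> pd.DataFrame:
    """Per-class area trajectories ``area_t = area_0 * rate^t`` (+ noise).

    Returns a tidy frame with columns ``class, year, area, unit``.  Yearly
    totals are renormalised to the (constant) total area; multiplicative
    lognormal noise with sd ``noise_sd`` (default 1%) perturbs each point.
    A grey model needs at least four observations, hence the years check.
    """
    if len(spec.years) < 4:
        raise ValueError("need >= 4 years: GM(1,1) requires at least 4 observations")
    if not 0 <= noise_sd <= 0.01 + 1e-12:
        raise ValueError("noise_sd must be within [0, 0.01] (<=1% multiplicative)")
    rng = np.random.default_rng(spec.seed + 1)
    if total_area is None:
        total_area = spec.grid_shape[0] * spec.grid_shape[1] * spec.cell_area_ha / 100.0  # km^2
    base = np.asarray(spec.class_fractions) * total_area
    rates = np.asarray(spec.trend_rates)
    y0 = spec.years[0]
    records = []
    for year in spec.years:
        t = year - y0
        areas = base * rates ** t
        if noise_sd > 0:
            areas = areas * rng.lognormal(mean=0.0, sigma=noise_sd, size=len(areas))
        areas = areas * (total_area / areas.sum())
        for code, a in zip(spec.codes, areas):
            records.append({"class": spec.legend.get(code, str(code)), "year": year,
                            "area": a, "unit": "km2"})
    return pd.DataFrame.from_records(records)


def generate_socioeconomic_series(years, seed: int = 0,
                                  identical: bool = False) -> pd.DataFrame:
    """Paired regional/national socio-economic indicator series.

    Emits, per year and per region (``regional``/``national``): Engel
    coefficient (fraction in (0,1)), per-capita GDP (USD), urbanization rate
    (fraction), population density (persons/km^2, > 1), grain yield (kg/ha)
    and grain price (USD/kg).  With ``identical=True`` both streams are
    equal, so every downstream correction factor is exactly 1.
    """
    years = list(years)
    if not years:
        raise ValueError("years must be non-empty")
    rng = np.random.default_rng(seed + 2)
    n = len(years)
    t = np.arange(n)

    def walk(start, rate, sd):
        drift = start * rate ** t
        if identical or sd == 0:
            return drift
        return drift * rng.lognormal(0.0, sd, size=n)

    records = []
    streams = {
        # start values loosely at national-scale magnitudes; regional stream
        # offset so ratios stay well inside [0.2, 5]
        "national": dict(engel=0.40, gdp=6000.0, urban=0.45, density=145.0,
                         yield_=5200.0, price=0.38),
        "regional": dict(engel=0.42, gdp=5200.0, urban=0.50, density=440.0,
                         yield_=4800.0, price=0.38),
    }
    for region, s in streams.items():
        if identical:
            s = streams["national"]
        engel = np.clip(walk(s["engel"], 0.99, 0.01), 0.05, 0.95)
        gdp = walk(s["gdp"], 1.06, 0.02)
        urban = np.clip(walk(s["urban"], 1.01, 0.01), 0.05, 0.95)
        density = np.maximum(walk(s["density"], 1.004, 0.005), 1.5)
        grain_yield = walk(s["yield_"], 1.005, 0.01)
        price = walk(s["price"], 1.0, 0.005)
        for i, year in enumerate(years):
            records.append({"year": year, "region": region,
                            "engel_coefficient": engel[i],
                            "per_capita_gdp": gdp[i],
                            "urbanization_rate": urban[i],
                            "population_density": density[i],
                            "grain_yield": grain_yield[i],
                            "grain_price": price[i]})
    return pd.DataFrame.from_records(records)


def evolve_landscape(landscape: CategoricalRaster, rules, n_changes: int,
                     seed: int = 0, restricted_mask: np.ndarray | None = None) -> CategoricalRaster:
    """Apply exactly ``n_changes`` rule-permitted single-cell transitions.

    Produces a ground-truth "later" map for transition-matrix estimation and
    allocation validation.  Restricted cells are never touched; each changed
    cell moves to a uniformly drawn permitted class different from its
    current one.
    """
    from .ca import TransitionRules  # local import to avoid a cycle

    if not isinstance(rules, TransitionRules):
        raise TypeError("rules must be a TransitionRules")
    rng = np.random.default_rng(seed + 3)
    grid = landscape.grid.copy()
    frozen = np.zeros(landscape.shape, dtype=bool) if restricted_mask is None else restricted_mask.astype(bool)

    changeable = np.zeros(landscape.shape, dtype=bool)
    targets_of: dict[int, np.ndarray] = {}
    for code in rules.codes:
        allowed = [j for j in rules.codes if j != code and rules.allows(code, j)]
        targets_of[code] = np.array(allowed, dtype=np.int64)
        if allowed:
            changeable |= (grid == code) & ~frozen
    candidates = np.flatnonzero(changeable.ravel())
    if n_changes > candidates.size:
        raise ValueError(
            f"n_changes={n_changes} exceeds the {candidates.size} changeable cells")
    chosen = rng.choice(candidates, size=n_changes, replace=False)
    flat = grid.ravel()
    for idx in chosen:
        opts = targets_of[int(flat[idx])]
        flat[idx] = rng.choice(opts)
    return CategoricalRaster(grid, landscape.cell_area_ha, dict(landscape.legend))
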