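"""Equivalent-factor ecosystem-service valuation with regional corrections.

The base model prices each land class by a per-hectare coefficient table
(11 ecosystem services x 8 land classes, USD/ha/yr), anchored by the unit
equivalent factor Ea = (1/7) * grain price * mean grain yield.  The regional
revision rescales the base value by three dimensionless factors:

* grain-yield factor      Q  = G_A / G_N
* socio-economic factor   D  = Pw * Pv, with willingness to pay
  Pw = L(EL_A) / L(EL_N) through the Peal (logistic) growth curve
  L(E) = 1 / (1 + exp(-(1/E - 3))) of the Engel coefficient, and ability to
  pay Pv = (pGDP_A / pGDP_N) * (U_A / U_N)
* resource-scarcity factor S = ln(P_A) / ln(P_N) on population densities

so the revised value is ESV = sum_i A_i * VC_i * Q * D * S — an exactly
linear rescaling of the base estimate.  Subscript A denotes the study area,
N the national reference.  The Engel coefficient is treated as a fraction in
(0, 1): on a percent scale 1/EL - 3 would be ~ -3 for any realistic value,
collapsing the curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

CLASS_COLUMNS = ["paddy_field", "unirrigated_field", "forest_land", "grass_land",
                 "water_area", "wet_land", "built_up_land", "unused_land"]
CATEGORIES = ["provisioning", "regulating", "supporting", "cultural"]


class ESVError(ValueError):
    pass


def load_coefficients() -> pd.DataFrame:
    """Packaged per-hectare valuation coefficients (service x class, USD/ha/yr).

    Indexed by service name with a ``category`` column and the eight land-class
    columns.
    """
    from importlib import resources

    with resources.files("lucsim.data").joinpath("esv_coefficients.csv").open() as fh:
        df = pd.read_csv(fh, index_col="service")
    missing = set(CLASS_COLUMNS) - set(df.columns)
    if missing or len(df) != 11:
        raise ESVError(f"coefficient table malformed (missing {sorted(missing)})")
    if not set(df["category"]) <= set(CATEGORIES):
        raise ESVError("unknown service category in coefficient table")
    return df


def coefficient_totals(vc: pd.DataFrame) -> pd.Series:
    """Per-class column totals of the coefficient table (USD/ha/yr)."""
    return vc[CLASS_COLUMNS].sum(axis=0)


def unit_equivalent_value(price: float, yields) -> float:
    """Unit value of the equivalent factor: Ea = (1/7) * p * mean(yields)."""
    yields = np.asarray(yields, dtype=float)
    if yields.size == 0:
        raise ESVError("need at least one crop yield")
    if price <= 0 or np.any(yields <= 0):
        raise ESVError("price and yields must be positive")
    return price * yields.mean() / 7.0


def grain_yield_factor(ga: float, gn: float) -> float:
    """Q = regional / national mean grain yield."""
    if ga <= 0 or gn <= 0:
        raise ESVError("grain yields must be positive")
    return ga / gn


def _peal_curve(engel: float) -> float:
    if not 0 < engel < 1:
        raise ESVError("Engel coefficient must be a fraction in (0, 1)")
    return 1.0 / (1.0 + np.exp(-(1.0 / engel - 3.0)))


def willingness_to_pay(el_a: float, el_n: float) -> float:
    """Pw = L(EL_A) / L(EL_N) with the Peal growth curve L."""
    return _peal_curve(el_a) / _peal_curve(el_n)


def ability_to_pay(pgdp_a: float, pgdp_n: float, u_a: float, u_n: float) -> float:
    """Pv = (pGDP_A / pGDP_N) * (U_A / U_N)."""
    if min(pgdp_a, pgdp_n, u_a, u_n) <= 0:
        raise ESVError("GDP and urbanization inputs must be positive")
    return (pgdp_a / pgdp_n) * (u_a / u_n)


def development_factor(pw: float, pv: float) -> float:
    """Socio-economic development factor D = Pw * Pv."""
    return pw * pv


def scarcity_factor(pa: float, pn: float) -> float:
    """Resource-scarcity factor S = ln(P_A) / ln(P_N) (densities > 1)."""
    if pa <= 1 or pn <= 1:
        raise ESVError("population densities must exceed 1 persons/km^2 "
                       "(log-ratio domain)")
    return float(np.log(pa) / np.log(pn))


@dataclass
class CorrectionFactors:
    Q: float
    Pw: float
    Pv: float
    S: float

    @property
    def D(self) -> float:
        return self.Pw * self.Pv

    @property
    def combined(self) -> float:
        return self.Q * self.D * self.S


def correction_factors(regional: dict, national: dict) -> CorrectionFactors:
    """All correction factors from paired regional/national indicator dicts.

    Expected keys: ``grain_yield, engel_coefficient, per_capita_gdp,
    urbanization_rate, population_density``.
    """
    return CorrectionFactors(
        Q=grain_yield_factor(regional["grain_yield"], national["grain_yield"]),
        Pw=willingness_to_pay(regional["engel_coefficient"], national["engel_coefficient"]),
        Pv=ability_to_pay(regional["per_capita_gdp"], national["per_capita_gdp"],
                          regional["urbanization_rate"], national["urbanization_rate"]),
        S=scarcity_factor(regional["population_density"], national["population_density"]),
    )


@dataclass
class ESVResult:
    """Valuation breakdown, in USD (scale via ``unit_divisor`` on report)."""

    per_class: pd.Series       # USD by land-class column name
    per_category: pd.Series    # USD by service category
    total: float

    def proportions(self) -> pd.Series:
        if self.total == 0:
            raise ESVError("zero total ESV: proportions undefined")
        return self.per_class / self.total * 100.0


def _areas_to_ha(areas: dict[str, float], unit: str) -> pd.Series:
    factor = {"ha": 1.0, "km2": 100.0}.get(unit)
    if factor is None:
        raise ESVError(f"unknown area unit '{unit}' (use 'ha' or 'km2')")
    s = pd.Series(areas, dtype=float) * factor
    unknown = set(s.index) - set(CLASS_COLUMNS)
    if unknown:
        raise ESVError(f"unknown land classes {sorted(unknown)}")
    if (s < 0).any():
        raise ESVError("areas must be nonnegative")
    return s


def base_esv(areas: dict[str, float], vc: pd.DataFrame, unit: str = "km2") -> ESVResult:
    """Unrevised valuation: ESV = sum_i A_i * VC_i.

    ``areas`` maps class names to areas in ``unit``; per-class values use the
    class's coefficient column total, per-category values sum the category's
    service rows over all classes.  Both breakdowns total identically.
    """
    a = _areas_to_ha(areas, unit)
    cols = [c for c in CLASS_COLUMNS if c in a.index]
    per_class = coefficient_totals(vc)[cols] * a[cols]
    cat = vc.groupby("category")[cols].sum()
    per_category = (cat * a[cols]).sum(axis=1).reindex(CATEGORIES).fillna(0.0)
    return ESVResult(per_class=per_class, per_category=per_category,
                     total=float(per_class.sum()))


def revised_esv(areas: dict[str, float], vc: pd.DataFrame,
                factors: CorrectionFactors, unit: str = "km2") -> ESVResult:
    """Regionally revised valuation: base ESV scaled by Q * D * S."""
    if min(factors.Q, factors.Pw, factors.Pv, factors.S) <= 0:
        raise ESVError("correction factors must be positive")
    base = base_esv(areas, vc, unit)
    f = factors.combined
    return ESVResult(per_class=base.per_class * f,
                     per_category=base.per_category * f,
                     total=base.total * f)


def growth_rate(earlier: float, later: float) -> float:
    """Relative change in percent: (later - earlier) / earlier * 100."""
    if earlier == 0:
        raise ESVError("growth rate undefined for a zero base value")
    return (later - earlier) / earlier * 100.0


def proportions(values: pd.Series) -> pd.Series:
    """Shares of the (signed) total, in percent; negatives allowed."""
    total = values.sum()
    if total == 0:
        raise ESVError("zero total: proportions undefined")
    return values / total * 100.0


def esv_report(results_by_year: dict[int, ESVResult],
               unit_divisor: float = 1e7) -> pd.DataFrame:
    """Trend table across years: per-class ESV, proportion and growth.

    Values are reported in units of ``unit_divisor`` USD (default 10^7 USD).
    Growth rates compare each year against the first.  Per-class proportions
    may be negative (built-up land detracts from the total).
    """
    unit_divisor = float(unit_divisor)
    years = sorted(results_by_year)
    if len(years) < 2:
        raise ESVError("trend report needs at least two years")
    rows = []
    y0 = years[0]
    for year in years:
        r = results_by_year[year]
        props = r.proportions()
        for cls in r.per_class.index:
            rows.append({"year": year, "class": cls,
                         "esv": r.per_class[cls] / unit_divisor,
                         "proportion_pct": props[cls],
                         "growth_from_first_pct":
                             growth_rate(results_by_year[y0].per_class[cls],
                                         r.per_class[cls])
                             if results_by_year[y0].per_class[cls] != 0 else np.nan})
        rows.append({"year": year, "class": "total",
                     "esv": r.total / unit_divisor,
                     "proportion_pct": 100.0,
                     "growth_from_first_pct": growth_rate(results_by_year[y0].total, r.total)})
    return pd.DataFrame(rows)
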