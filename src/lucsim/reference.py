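"""Loaders for the packaged reference tables of the Anhui Province study.

These CSVs transcribe the published study's printed tables: the per-hectare
valuation coefficients and their printed column totals, the ecological-
optimization conversion rules, the 2018 validation confusion-matrix counts,
the demand-model evaluation pairs (predicted vs actual areas for both
forecasting models), the observed/simulated land-use areas, and the
published per-class and per-category valuation series.  They serve as
inputs for reproducing the study's derived statistics and as fixtures for
the test suite.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .ca import TransitionRules, load_rules


def _read(name: str, **kwargs) -> pd.DataFrame:
    with resources.files("lucsim.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, **kwargs)


def ecological_optimization_rules() -> TransitionRules:
    """The 7x7 binary conversion-permission matrix of the ecological scenario."""
    with resources.as_file(resources.files("lucsim.data")
                           .joinpath("conversion_rules_ecological_optimization.csv")) as p:
        return load_rules(p)


def coefficient_printed_totals() -> pd.Series:
    """Printed per-class coefficient column totals (USD/ha/yr)."""
    df = _read("esv_coefficient_totals.csv", index_col="class")
    return df["total"]


def validation_confusion_counts() -> pd.DataFrame:
    """2018 validation sample counts: simulated rows x actual columns."""
    df = _read("validation_confusion_2018.csv", index_col="simulated_class")
    df.index.name = "simulated"
    df.columns.name = "actual"
    return df


def demand_model_evaluation() -> pd.DataFrame:
    """Predicted vs actual areas (km^2) for both demand models, 2015/2018."""
    return _read("demand_model_evaluation.csv")


def landuse_areas_km2() -> pd.DataFrame:
    """Observed 2018 and simulated 2025/2030 per-class areas (km^2)."""
    return _read("landuse_areas_km2.csv", index_col="class")


def esv_by_class_1e7usd() -> pd.DataFrame:
    """Published per-class valuation series, 10^7 USD, 1995-2030."""
    return _read("esv_by_class_1e7usd.csv", index_col="class")


def esv_by_category_1e7usd() -> pd.DataFrame:
    """Published per-category valuation values (10^7 USD) where printed."""
    return _read("esv_by_category_1e7usd.csv")
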