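"""Land-use demand forecasting: grey GM(1,1) and Markov-chain models.

GM(1,1) fits an exponential trend to the accumulated (AGO) series of a short
positive time series:

    x1 = cumsum(x0);   z1(k) = (x1(k) + x1(k-1)) / 2
    x0(k) = -a z1(k) + b           (ordinary least squares for a, b)
    x̂0(1) = x0(1);  x̂0(k) = (x0(1) - b/a)(1 - e^a) e^{-a(k-1)},  k >= 2

The forecast quality is graded with the posterior-difference test (ratio C
of residual to data standard deviation, and small-error possibility P),
banded into accuracy levels 1 (best) to 4 (unqualified).  The Markov model
projects a class-area state vector through an empirically estimated
row-stochastic transition matrix, S_{t+k} = S_t P^k.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .raster import CategoricalRaster

#: posterior-difference bands: level -> (C upper bound, P lower bound)
ACCURACY_BANDS = {1: (0.35, 0.95), 2: (0.50, 0.80), 3: (0.65, 0.70)}


class DemandError(ValueError):
    pass


@dataclass
class GreyModelFit:
    """GM(1,1) parameters and in-sample restored series."""

    a: float                 # development coefficient (1/step)
    b: float                 # grey input (area/step)
    x0_1: float              # first observation
    fitted: np.ndarray       # restored series x̂0(k), same length as input
    residuals: np.ndarray    # x0(k) - x̂0(k)
    series: np.ndarray
    unstable: bool = False   # |a| >= 2 flag

    def restore(self, k: np.ndarray) -> np.ndarray:
        """Restored-series formula at 1-based indices ``k`` (k >= 2)."""
        if abs(self.a) < 1e-12:
            return np.full_like(np.asarray(k, dtype=float), self.b)
        return (self.x0_1 - self.b / self.a) * (1 - np.exp(self.a)) * np.exp(-self.a * (np.asarray(k) - 1))


@dataclass
class AccuracyTestResult:
    C: float
    P: float
    level: int


def fit_gm11(series) -> GreyModelFit:
    """Fit a GM(1,1) grey model to a short positive series (n >= 4)."""
    x0 = np.asarray(series, dtype=float)
    if x0.ndim != 1 or len(x0) < 4:
        raise DemandError("GM(1,1) needs a 1-D series with at least 4 observations")
    if np.any(x0 <= 0):
        raise DemandError("GM(1,1) is undefined for nonpositive values")
    x1 = np.cumsum(x0)
    z1 = 0.5 * (x1[1:] + x1[:-1])
    B = np.column_stack([-z1, np.ones_like(z1)])
    (a, b), *_ = np.linalg.lstsq(B, x0[1:], rcond=None)
    unstable = abs(a) >= 2
    if unstable:
        warnings.warn(f"GM(1,1) development coefficient |a|={abs(a):.3g} >= 2: "
                      "model unstable", RuntimeWarning, stacklevel=2)
    fit = GreyModelFit(a=float(a), b=float(b), x0_1=float(x0[0]),
                       fitted=np.empty(0), residuals=np.empty(0),
                       series=x0, unstable=unstable)
    k = np.arange(2, len(x0) + 1)
    fitted = np.concatenate([[x0[0]], fit.restore(k)])
    fit.fitted = fitted
    fit.residuals = x0 - fitted
    return fit


def predict_gm11(fit: GreyModelFit, horizon: int) -> np.ndarray:
    """Extend the restored series ``horizon`` steps beyond the sample."""
    if horizon < 1:
        raise DemandError("forecast horizon must be >= 1")
    n = len(fit.series)
    k = np.arange(n + 1, n + horizon + 1)
    return fit.restore(k)


def posterior_difference_test(fit: GreyModelFit) -> AccuracyTestResult:
    """Grade a grey-model fit by the posterior-difference test.

    C = S2/S1 where S1, S2 are the population standard deviations of the
    data and the residuals; P is the fraction of residuals within
    0.6745*S1 of the mean residual.  The level is the worse of the C band
    and the P band; a zero-variance series is graded level 1 with C = 0
    (perfect predictability is the limiting best case).
    """
    e = fit.residuals
    s1 = float(np.std(fit.series))   # population (1/n) convention
    s2 = float(np.std(e))
    if s1 == 0:
        return AccuracyTestResult(C=0.0, P=1.0, level=1)
    C = s2 / s1
    P = float(np.mean(np.abs(e - e.mean()) < 0.6745 * s1))

    def band(value, key):
        for level, (c_max, p_min) in ACCURACY_BANDS.items():
            if (key == "C" and value < c_max) or (key == "P" and value > p_min):
                return level
        return 4

    return AccuracyTestResult(C=C, P=P, level=max(band(C, "C"), band(P, "P")))


def estimate_transition_matrix(map_t1: CategoricalRaster,
                               map_t2: CategoricalRaster) -> pd.DataFrame:
    """Empirical class-transition probability matrix between two dates.

    ``P[i, j]`` is the fraction of class-``i`` cells at t1 that are class
    ``j`` at t2.  Classes absent at t1 get identity rows so the matrix stays
    row-stochastic.
    """
    if map_t1.shape != map_t2.shape:
        raise DemandError("rasters are not aligned")
    if map_t1.legend != map_t2.legend:
        raise DemandError("legend mismatch between the two rasters")
    codes = sorted(map_t1.legend)
    k = len(codes)
    code_pos = {c: i for i, c in enumerate(codes)}
    counts = np.zeros((k, k))
    a = map_t1.grid.ravel()
    b = map_t2.grid.ravel()
    valid = (a != -9999) & (b != -9999)
    idx = np.ravel_multi_index(
        (np.vectorize(code_pos.get)(a[valid]), np.vectorize(code_pos.get)(b[valid])), (k, k))
    counts = np.bincount(idx, minlength=k * k).reshape(k, k).astype(float)
    rowsum = counts.sum(axis=1)
    P = np.eye(k)
    nz = rowsum > 0
    P[nz] = counts[nz] / rowsum[nz, None]
    names = [map_t1.legend[c] for c in codes]
    return pd.DataFrame(P, index=names, columns=names)


def predict_markov(S, P: pd.DataFrame | np.ndarray, steps: int = 1) -> np.ndarray:
    """Project a class-area row vector ``steps`` transitions ahead.

    Uses the row-stochastic orientation: S_{t+k} = S_t @ P^k, which
    conserves total area.
    """
    S = np.asarray(S, dtype=float)
    Pm = P.to_numpy() if isinstance(P, pd.DataFrame) else np.asarray(P, dtype=float)
    if steps < 1:
        raise DemandError("steps must be >= 1")
    if Pm.shape[0] != Pm.shape[1] or Pm.shape[0] != S.shape[0]:
        raise DemandError("dimension mismatch between state and matrix")
    if np.any(Pm < -1e-12) or np.any(np.abs(Pm.sum(axis=1) - 1) > 1e-9):
        raise DemandError("transition matrix is not row-stochastic")
    return S @ np.linalg.matrix_power(Pm, steps)


def compare_models(pred_a, pred_b, actual, labels=None,
                   names: tuple[str, str] = ("gm11", "markov")) -> pd.DataFrame:
    """Per-class relative-difference comparison of two demand forecasts.

    ``d = (pred - actual) / actual * 100`` for each model; ``accuracy_gap``
    is ``|d_b| - |d_a|`` (positive when model *a* is closer).  Classes with
    zero actual area get NaN differences.  The model with the smaller mean
    absolute difference is flagged in ``df.attrs['selected']``.
    """
    pred_a = np.asarray(pred_a, dtype=float)
    pred_b = np.asarray(pred_b, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if not (pred_a.shape == pred_b.shape == actual.shape):
        raise DemandError("class vectors differ in length")
    with np.errstate(divide="ignore", invalid="ignore"):
        d_a = np.where(actual != 0, (pred_a - actual) / actual * 100, np.nan)
        d_b = np.where(actual != 0, (pred_b - actual) / actual * 100, np.nan)
    df = pd.DataFrame({
        "class": labels if labels is not None else np.arange(len(actual)),
        f"pred_{names[0]}": pred_a, f"pred_{names[1]}": pred_b, "actual": actual,
        f"diff_{names[0]}_pct": d_a, f"diff_{names[1]}_pct": d_b,
        "accuracy_gap": np.abs(d_b) - np.abs(d_a),
    })
    mean_a = np.nanmean(np.abs(d_a))
    mean_b = np.nanmean(np.abs(d_b))
    df.attrs["selected"] = names[0] if mean_a <= mean_b else names[1]
    return df


@dataclass
class DemandPolicy:
    """How forecast areas become CA cell-count targets.

    ``fold_unused_into_built_up`` merges the (small, transient) unused-land
    class into built-up land before allocation; ``protection_floor_km2``, if
    set, is the minimum combined cultivated area (paddy + unirrigated).
    """

    fold_unused_into_built_up: bool = True
    protection_floor_km2: float | None = None
    unused_code: int = 8
    built_up_code: int = 7
    cultivated_codes: tuple[int, ...] = (1, 2)


def build_demand(forecast: dict[int, float], cell_area_ha: float, total_cells: int,
                 policy: DemandPolicy = DemandPolicy()) -> dict[int, int]:
    """Convert per-class forecast areas (km^2) to integer cell-count targets.

    Largest-remainder rounding guarantees the targets sum exactly to
    ``total_cells``.  The unused-land class is folded into built-up land when
    the policy says so, and the cultivated-land protection floor is checked
    on the forecast areas.
    """
    forecast = dict(forecast)
    if any(v < 0 for v in forecast.values()):
        raise DemandError("forecast areas must be nonnegative")
    if policy.protection_floor_km2 is not None:
        cultivated = sum(forecast.get(c, 0.0) for c in policy.cultivated_codes)
        if cultivated < policy.protection_floor_km2:
            raise DemandError(
                f"cultivated-land protection floor violated: {cultivated:.2f} km2 "
                f"< floor {policy.protection_floor_km2:.2f} km2")
    if policy.fold_unused_into_built_up and policy.unused_code in forecast:
        forecast[policy.built_up_code] = (forecast.get(policy.built_up_code, 0.0)
                                          + forecast.pop(policy.unused_code))
    codes = sorted(forecast)
    areas = np.array([forecast[c] for c in codes], dtype=float)
    if areas.sum() <= 0:
        raise DemandError("total forecast area must be positive")
    exact = areas / areas.sum() * total_cells
    base = np.floor(exact).astype(int)
    short = total_cells - base.sum()
    if short < 0:
        raise DemandError("targets exceed grid capacity")
    order = np.argsort(-(exact - base))
    base[order[:short]] += 1
    return {c: int(n) for c, n in zip(codes, base)}
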