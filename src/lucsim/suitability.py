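"""Occurrence-probability (suitability) estimation from driving factors.

A shallow feed-forward neural network maps normalized driving-factor vectors
to per-class occurrence probabilities (softmax output, so the per-cell
probabilities sum to one).  Factors are screened per class with binary
logistic regression scored by ROC area: a factor set with AUC >= 0.5 is
considered usable.  Multi-class factor layers are fed as normalized numeric
codes, mirroring common practice for categorical drivers in land-change
models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.neural_network import MLPClassifier

from .raster import CategoricalRaster, FactorStack


class SuitabilityError(ValueError):
    pass


def normalize_stack(raw: FactorStack) -> FactorStack:
    """Min–max rescale every layer to [0, 1].

    Constant layers map to 0.5 everywhere; NaN (nodata) is propagated.
    Idempotent: already-normalized layers are unchanged.
    """
    out = np.empty_like(raw.layers)
    for i, layer in enumerate(raw.layers):
        finite = np.isfinite(layer)
        if not finite.any():
            raise SuitabilityError(f"layer '{raw.names[i]}' is all nodata")
        lo, hi = layer[finite].min(), layer[finite].max()
        if hi == lo:
            out[i] = np.where(finite, 0.5, np.nan)
        else:
            out[i] = np.where(finite, (layer - lo) / (hi - lo), np.nan)
    return FactorStack(out, list(raw.names), list(raw.kinds))


@dataclass
class TrainingSet:
    X: np.ndarray            # (n, k) factor vectors
    y: np.ndarray            # (n,) class codes
    factor_names: list[str]
    cell_index: np.ndarray   # flat indices of the sampled cells


def sample_training(landuse: CategoricalRaster, factors: FactorStack, n: int,
                    strategy: str = "uniform", seed: int = 0) -> TrainingSet:
    """Draw ``n`` training cells (factor vector, class label), seeded.

    ``uniform`` samples cells without replacement; ``stratified`` draws
    per-class counts proportional to class areas (classes absent from the map
    are skipped with a warning-free no-op, per contract largest classes first).
    """
    if landuse.shape != factors.shape:
        raise SuitabilityError("land-use raster and factor stack are not aligned")
    total = landuse.grid.size
    if n > total:
        raise SuitabilityError("sample size exceeds cell count")
    rng = np.random.default_rng(seed)
    flat = landuse.grid.ravel()
    if strategy == "uniform":
        idx = rng.choice(total, size=n, replace=False)
    elif strategy == "stratified":
        counts = {c: int((flat == c).sum()) for c in sorted(landuse.legend)}
        present = {c: m for c, m in counts.items() if m > 0}
        quota = {c: n * m / total for c, m in present.items()}
        base = {c: int(np.floor(q)) for c, q in quota.items()}
        short = n - sum(base.values())
        for c in sorted(present, key=lambda c: quota[c] - base[c], reverse=True)[:short]:
            base[c] += 1
        parts = []
        for c, m in base.items():
            cells = np.flatnonzero(flat == c)
            parts.append(rng.choice(cells, size=min(m, cells.size), replace=False))
        idx = np.concatenate(parts)
    else:
        raise SuitabilityError(f"unknown sampling strategy '{strategy}'")
    X = factors.layers.reshape(factors.n_layers, -1)[:, idx].T
    return TrainingSet(X=X, y=flat[idx], factor_names=list(factors.names),
                       cell_index=idx)


@dataclass
class SuitabilityModel:
    clf: MLPClassifier
    factor_names: list[str]

    @property
    def classes(self) -> np.ndarray:
        return self.clf.classes_


def train_suitability_ann(train: TrainingSet, hidden_units: int = 12,
                          epochs: int = 300, seed: int = 0) -> SuitabilityModel:
    """Train the single-hidden-layer suitability network.

    Softmax output guarantees per-cell probabilities summing to one; training
    is deterministic given the seed.
    """
    if len(np.unique(train.y)) < 2:
        raise SuitabilityError("training set is degenerate: fewer than 2 classes")
    clf = MLPClassifier(hidden_layer_sizes=(hidden_units,), max_iter=epochs,
                        random_state=seed, solver="adam", alpha=1e-4)
    import warnings
    with warnings.catch_warnings():
        from sklearn.exceptions import ConvergenceWarning
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(train.X, train.y)
    return SuitabilityModel(clf=clf, factor_names=list(train.factor_names))


def predict_suitability(model: SuitabilityModel, factors: FactorStack,
                        all_codes=None) -> dict[int, np.ndarray]:
    """Full-grid occurrence-probability surfaces, one per class.

    Classes the model never saw get zero probability everywhere.  Cells with
    any nodata factor value carry NaN.
    """
    if list(factors.names) != model.factor_names:
        missing = [n for n in model.factor_names if n not in factors.names]
        raise SuitabilityError(f"factor layers do not match training; missing {missing}")
    k, (rows, cols) = factors.n_layers, factors.shape
    X = factors.layers.reshape(k, -1).T
    ok = np.all(np.isfinite(X), axis=1)
    proba = np.full((X.shape[0], len(model.classes)), np.nan)
    if ok.any():
        proba[ok] = model.clf.predict_proba(X[ok])
    codes = list(all_codes) if all_codes is not None else [int(c) for c in model.classes]
    stack: dict[int, np.ndarray] = {}
    for code in codes:
        if code in model.classes:
            j = int(np.flatnonzero(model.classes == code)[0])
            stack[code] = proba[:, j].reshape(rows, cols)
        else:
            stack[code] = np.where(ok.reshape(rows, cols), 0.0, np.nan)
    return stack


@dataclass
class FactorScreenResult:
    target_class: int
    intercept: float
    coefficients: dict[str, float]
    roc_auc: float
    usable: bool                 # AUC >= 0.5
    complete_separation: bool    # AUC == 1 on the fitted sample


def screen_factors_logistic(landuse: CategoricalRaster, factors: FactorStack,
                            target_class: int, seed: int = 0,
                            sample_fraction: float = 0.02) -> FactorScreenResult:
    """Binary (class vs rest) logistic screening scored by ROC AUC.

    Fits on a sparse uniform sample of cells (default 2%) and reports the
    intercept, per-factor coefficients and the rank-statistic AUC.
    """
    flat = landuse.grid.ravel()
    if not (flat == target_class).any():
        raise SuitabilityError(f"target class {target_class} absent from the map")
    n = max(int(round(sample_fraction * flat.size)), 50)
    n = min(n, flat.size)
    train = sample_training(landuse, factors, n, strategy="uniform", seed=seed)
    y = (train.y == target_class).astype(int)
    if y.min() == y.max():  # sample missed one side; fall back to the full grid
        X = factors.layers.reshape(factors.n_layers, -1).T
        y = (flat == target_class).astype(int)
    else:
        X = train.X
    clf = LogisticRegression(max_iter=1000)
    clf.fit(X, y)
    scores = clf.decision_function(X)
    auc = float(roc_auc_score(y, scores))
    return FactorScreenResult(
        target_class=target_class,
        intercept=float(clf.intercept_[0]),
        coefficients=dict(zip(factors.names, clf.coef_[0].tolist())),
        roc_auc=auc,
        usable=auc >= 0.5,
        complete_separation=auc == 1.0,
    )
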