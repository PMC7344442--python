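"""Constrained cellular-automaton allocation and map-accuracy assessment.

The engine distributes demanded per-class cell counts over the grid.  Each
sweep combines, per cell and candidate class j:

    score(cell, j) = suitability_j(cell) * neighborhood_j(cell)
                     * inertia_j * allow[initial(cell), j]

where the neighborhood term is the Moore-window density of class j, the
adaptive inertia strengthens (relaxes) a class's persistence as its
under-(over-)allocation worsens, and the binary conversion-rules matrix plus
a restricted mask encode the scenario.  The next class of a visited cell is
drawn by roulette-wheel selection from the renormalized scores; a conversion
is committed only while it moves both classes toward their targets, so cell
count is conserved every sweep and the allocation converges to the demand
within a tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage


class CAError(ValueError):
    pass


class TransitionRules:
    """Binary from-class x to-class permission matrix.

    The diagonal must be all ones (a class may always persist).  Built from a
    square 0/1 CSV whose header row and first column carry class names.
    """

    def __init__(self, allow: pd.DataFrame, codes: list[int] | None = None):
        a = allow.to_numpy()
        if a.shape[0] != a.shape[1]:
            raise CAError("rules matrix must be square")
        if not np.isin(a, (0, 1)).all():
            raise CAError("rules matrix entries must be 0 or 1")
        if not (np.diag(a) == 1).all():
            raise CAError("rules diagonal must be all 1 (classes may persist)")
        self.table = allow.astype(int)
        self.codes = codes if codes is not None else list(range(1, len(allow) + 1))
        self._pos = {c: i for i, c in enumerate(self.codes)}
        if a.sum() == len(allow):  # identity: only persistence permitted
            import warnings
            warnings.warn("rules permit no change (identity matrix)", UserWarning,
                          stacklevel=2)

    def allows(self, from_code: int, to_code: int) -> bool:
        return bool(self.table.iat[self._pos[from_code], self._pos[to_code]])

    @property
    def matrix(self) -> np.ndarray:
        return self.table.to_numpy()


def load_rules(path: str | Path) -> TransitionRules:
    """Load a conversion-rules CSV (header row + ``from_class`` column)."""
    df = pd.read_csv(path, index_col=0)
    if list(df.index) != list(df.columns):
        missing = set(df.columns).symmetric_difference(df.index)
        raise CAError(f"rules row/column class names differ: {sorted(missing)}")
    if not df.map(lambda v: v in (0, 1)).all().all():
        raise CAError("rules matrix entries must be 0 or 1")
    return TransitionRules(df)


@dataclass
class CAParams:
    """Tunable CA-engine constants (all config-exposed)."""

    neighborhood_size: int = 3       # odd Moore-window edge, in cells
    max_iterations: int = 100
    demand_tolerance: int | None = None  # cells; default 0.1% of the grid
    inertia_floor: float = 1e-3
    seed: int = 0
    candidate_mode: str = "all"      # "all" or "mismatched" cells per sweep

    def __post_init__(self) -> None:
        if self.neighborhood_size < 3 or self.neighborhood_size % 2 == 0:
            raise CAError("neighborhood_size must be odd and >= 3")

    def tolerance_for(self, n_cells: int) -> int:
        if self.demand_tolerance is not None:
            return self.demand_tolerance
        return max(1, int(round(0.001 * n_cells)))


def neighborhood_effect(landuse, cls: int, params: CAParams = CAParams()) -> np.ndarray:
    """Moore-window density of class ``cls`` around each cell.

    Fraction of same-class cells within the size x size window, excluding the
    center cell; windows are truncated at the grid edge.
    """
    grid = landuse.grid if hasattr(landuse, "grid") else np.asarray(landuse)
    if hasattr(landuse, "legend") and cls not in landuse.legend:
        raise CAError(f"class {cls} not in legend")
    size = params.neighborhood_size
    ind = (grid == cls).astype(float)
    kernel = np.ones((size, size))
    counts = ndimage.correlate(ind, kernel, mode="constant", cval=0.0)
    denom = ndimage.correlate(np.ones_like(ind), kernel, mode="constant", cval=0.0)
    return (counts - ind) / (denom - 1.0)


def adaptive_inertia(prev_inertia: float, d_prev: float, d_prev2: float,
                     inertia_floor: float = 1e-3) -> float:
    """Update a class's inertia from its last two demand gaps.

    ``d = demand_target - allocated``.  If the gap magnitude did not grow the
    inertia is unchanged.  A worsening under-allocation (d > 0) scales the
    inertia up by the gap ratio; a worsening over-allocation (d < 0) scales
    it down, releasing cells of that class.  Zero previous gaps leave the
    inertia unchanged; the result never drops below ``inertia_floor``.
    """
    if abs(d_prev) <= abs(d_prev2) or d_prev2 == 0 or d_prev == 0:
        new = prev_inertia
    elif d_prev < 0:
        new = prev_inertia * abs(d_prev2) / abs(d_prev)
    else:
        new = prev_inertia * abs(d_prev) / abs(d_prev2)
    return max(new, inertia_floor)


def combined_probability(suit: dict[int, np.ndarray], neigh: dict[int, np.ndarray],
                         inertia: dict[int, float], rules: TransitionRules,
                         current, mask: np.ndarray | None = None,
                         initial=None) -> np.ndarray:
    """Per-cell candidate-class distribution, shape (k, rows, cols).

    Scores multiply suitability, neighborhood density, class inertia and the
    binary permission of the transition from the *initial* map (so chained
    conversions cannot launder a forbidden one).  Frozen cells and cells with
    an all-zero score vector get a point mass on their current class.
    """
    cur = current.grid if hasattr(current, "grid") else np.asarray(current)
    ini = cur if initial is None else (initial.grid if hasattr(initial, "grid") else np.asarray(initial))
    codes = rules.codes
    k = len(codes)
    rows, cols = cur.shape
    scores = np.zeros((k, rows, cols))
    allow = rules.matrix.astype(float)
    pos = {c: i for i, c in enumerate(codes)}
    ini_pos = np.vectorize(pos.get)(ini)
    for j, code in enumerate(codes):
        permitted = allow[ini_pos, j]
        scores[j] = suit[code] * neigh[code] * inertia[code] * permitted
    total = scores.sum(axis=0)
    dead = total <= 0
    frozen = np.zeros((rows, cols), dtype=bool) if mask is None else mask.astype(bool)
    out = np.zeros_like(scores)
    ok = ~(dead | frozen)
    with np.errstate(invalid="ignore", divide="ignore"):
        out[:, ok] = scores[:, ok] / total[ok]
    # point mass on the current class where frozen or degenerate
    fallback = dead | frozen
    if fallback.any():
        cur_pos = np.vectorize(pos.get)(cur)
        r, c = np.nonzero(fallback)
        out[cur_pos[r, c], r, c] = 1.0
    return out


def roulette_select(distribution, rng: np.random.Generator) -> int:
    """Draw one class index with probability proportional to its score."""
    p = np.asarray(distribution, dtype=float)
    if abs(p.sum() - 1.0) > 1e-6:
        raise CAError("distribution must sum to 1")
    return int(rng.choice(len(p), p=p / p.sum()))


def _feasible(rules: TransitionRules, counts: dict[int, int], demand: dict[int, int],
              frozen_counts: dict[int, int]) -> None:
    """Max-flow feasibility of the demanded composition under the rules.

    Surpluses of movable (non-frozen) cells must be routable to deficit
    classes along permitted direct transitions.
    """
    import networkx as nx

    g = nx.DiGraph()
    deficit_total = 0
    for c in rules.codes:
        surplus = counts.get(c, 0) - demand.get(c, 0)
        movable = counts.get(c, 0) - frozen_counts.get(c, 0)
        if demand.get(c, 0) < frozen_counts.get(c, 0):
            raise CAError(f"demand for class {c} below its frozen cell count")
        if surplus > 0:
            g.add_edge("src", f"s{c}", capacity=min(surplus, movable))
        elif surplus < 0:
            g.add_edge(f"d{c}", "snk", capacity=-surplus)
            deficit_total += -surplus
        for j in rules.codes:
            if j != c and rules.allows(c, j):
                g.add_edge(f"s{c}", f"d{j}")
    if deficit_total == 0:
        return
    if "src" not in g or "snk" not in g:
        raise CAError("infeasible demand: no donor classes available")
    flow = nx.maximum_flow_value(g, "src", "snk")
    if flow < deficit_total:
        raise CAError("infeasible demand under the conversion rules and mask "
                      f"(routable {flow} of {deficit_total} deficit cells)")


def run_allocation(initial, suit: dict[int, np.ndarray], rules: TransitionRules,
                   mask: np.ndarray | None, demand_targets: dict[int, int],
                   params: CAParams = CAParams()) -> tuple:
    """Iterate the CA until every class matches its demand within tolerance.

    Returns ``(final_map, log)`` where the log is a tidy frame with one row
    per (sweep, class): allocated count, target and inertia.  Raises before
    iterating if the demand is infeasible under the rules and mask.
    """
    from .raster import CategoricalRaster

    grid = initial.grid.copy()
    rows, cols = grid.shape
    n_cells = grid.size
    frozen = np.zeros((rows, cols), dtype=bool) if mask is None else mask.astype(bool)
    codes = rules.codes
    if sum(demand_targets.get(c, 0) for c in codes) != n_cells:
        raise CAError("demand must sum to the total cell count")
    counts = {c: int((grid == c).sum()) for c in codes}
    frozen_counts = {c: int(((grid == c) & frozen).sum()) for c in codes}
    _feasible(rules, counts, demand_targets, frozen_counts)

    rng = np.random.default_rng(params.seed)
    tol = params.tolerance_for(n_cells)
    inertia = {c: 1.0 for c in codes}
    gaps_hist: list[dict[int, int]] = []
    log_rows = []
    pos = {c: i for i, c in enumerate(codes)}
    landuse_view = initial.copy()

    for sweep in range(1, params.max_iterations + 1):
        gaps = {c: demand_targets.get(c, 0) - counts[c] for c in codes}
        if all(abs(g) <= tol for g in gaps.values()):
            break
        if sweep >= 3:
            for c in codes:
                inertia[c] = adaptive_inertia(inertia[c], gaps_hist[-1][c],
                                              gaps_hist[-2][c], params.inertia_floor)
        gaps_hist.append(gaps)
        landuse_view.grid = grid
        neigh = {c: neighborhood_effect(landuse_view, c, params) for c in codes}
        dist = combined_probability(suit, neigh, inertia, rules, landuse_view,
                                    mask=frozen, initial=initial)
        # vectorized roulette: one uniform per cell against the class CDF
        cdf = np.cumsum(dist, axis=0)
        u = rng.random((rows, cols))
        hit = u[None, :, :] < cdf
        draws = hit.argmax(axis=0)
        draws[~hit.any(axis=0)] = len(codes) - 1  # guard float round-off at the tail

        if params.candidate_mode == "mismatched":
            over = {c for c in codes if counts[c] > demand_targets.get(c, 0)}
            cand = np.isin(grid, list(over)) & ~frozen
        else:
            cand = ~frozen
        order = rng.permutation(np.flatnonzero(cand.ravel()))
        flat = grid.ravel()
        draw_flat = draws.ravel()
        for idx in order:
            c_from = int(flat[idx])
            c_to = codes[int(draw_flat[idx])]
            if c_to == c_from:
                continue
            if counts[c_from] <= demand_targets.get(c_from, 0):
                continue
            if counts[c_to] >= demand_targets.get(c_to, 0):
                continue
            flat[idx] = c_to
            counts[c_from] -= 1
            counts[c_to] += 1
        for c in codes:
            log_rows.append({"sweep": sweep, "class": c, "allocated": counts[c],
                             "target": demand_targets.get(c, 0), "inertia": inertia[c]})
        assert sum(counts.values()) == n_cells

    final = CategoricalRaster(grid, initial.cell_area_ha, dict(initial.legend))
    log = pd.DataFrame(log_rows, columns=["sweep", "class", "allocated", "target", "inertia"])
    return final, log


def sample_cells(raster, fraction: float, rng: np.random.Generator) -> np.ndarray:
    """Uniform without-replacement sample of flat cell indices."""
    if not 0 < fraction <= 1:
        raise CAError("fraction must be in (0, 1]")
    n_total = raster.grid.size if hasattr(raster, "grid") else np.asarray(raster).size
    n = int(round(fraction * n_total))
    return rng.choice(n_total, size=n, replace=False)


@dataclass
class ConfusionMatrix:
    """Cross-tabulation of actual vs simulated labels with accuracy metrics."""

    counts: pd.DataFrame          # simulated rows x actual columns
    overall_accuracy: float       # trace / N
    kappa: float
    users_accuracy: pd.Series     # per simulated class (row-wise)
    producers_accuracy: pd.Series  # per actual class (column-wise)

    @property
    def n(self) -> int:
        return int(self.counts.to_numpy().sum())


def confusion_from_counts(counts: pd.DataFrame) -> ConfusionMatrix:
    """Accuracy metrics from a ready-made simulated x actual count table.

    kappa = (p_o - p_e) / (1 - p_e) with p_e = sum(row_i * col_i) / N^2.
    """
    m = counts.to_numpy(dtype=float)
    n = m.sum()
    if n == 0:
        raise CAError("empty confusion matrix")
    p_o = np.trace(m) / n
    p_e = float((m.sum(axis=1) * m.sum(axis=0)).sum()) / n ** 2
    kappa = (p_o - p_e) / (1 - p_e) if p_e < 1 else 1.0
    with np.errstate(invalid="ignore", divide="ignore"):
        users = pd.Series(np.diag(m) / m.sum(axis=1), index=counts.index)
        producers = pd.Series(np.diag(m) / m.sum(axis=0), index=counts.columns)
    return ConfusionMatrix(counts=counts, overall_accuracy=float(p_o),
                           kappa=float(kappa), users_accuracy=users,
                           producers_accuracy=producers)


def assess_accuracy(actual, simulated, labels=None) -> ConfusionMatrix:
    """Confusion matrix + overall accuracy and kappa from label vectors."""
    actual = np.asarray(actual).ravel()
    simulated = np.asarray(simulated).ravel()
    if actual.size == 0:
        raise CAError("empty label vectors")
    if actual.shape != simulated.shape:
        raise CAError("label vectors differ in length")
    if labels is None:
        labels = sorted(set(actual.tolist()) | set(simulated.tolist()))
    k = len(labels)
    lpos = {lab: i for i, lab in enumerate(labels)}
    idx = np.array([lpos[s] * k + lpos[a] for s, a in zip(simulated, actual)])
    m = np.bincount(idx, minlength=k * k).reshape(k, k)
    counts = pd.DataFrame(m, index=labels, columns=labels)
    counts.index.name = "simulated"
    counts.columns.name = "actual"
    return confusion_from_counts(counts)
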