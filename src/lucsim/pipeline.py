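"""Seeded end-to-end orchestration of the analysis stages.

Stage order mirrors the study framework: synthetic inputs -> demand
forecasting (grey vs Markov) -> factor screening and suitability training ->
constrained CA allocation (validated against a held-out later map) -> future
allocation -> valuation.  Every stage derives its randomness from the global
seed through fixed offsets, persists its artifacts under the configured
output directory, and appends a line to ``run.log``; ``run_all`` finishes by
writing SHA-256 checksums of every artifact so a rerun can be compared
byte-for-byte.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd

from . import ca, demand, esv, raster, reference, suitability, synthetic
from .config import PipelineConfig

CODES = list(range(1, 9))
NAMES = raster.DEFAULT_LEGEND


def _log(cfg: PipelineConfig, message: str) -> None:
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "run.log", "a") as fh:
        fh.write(f"[seed={cfg.seed} hash={cfg.hash()}] {message}\n")


def _rules(cfg: PipelineConfig) -> ca.TransitionRules:
    if cfg.rules_path:
        return ca.load_rules(cfg.rules_path)
    return reference.ecological_optimization_rules()


def _scenario_spec(cfg: PipelineConfig) -> synthetic.SyntheticScenarioSpec:
    s = cfg.synthetic
    return synthetic.SyntheticScenarioSpec(
        grid_shape=tuple(s.grid_shape), n_classes=len(s.class_fractions),
        cell_area_ha=s.cell_area_ha, autocorrelation_scale=s.autocorrelation_scale,
        class_fractions=tuple(s.class_fractions), trend_rates=tuple(s.trend_rates),
        years=tuple(s.years), seed=cfg.child_seed("landscape"))


def _fold_unused(grid: np.ndarray) -> np.ndarray:
    """All unused land is treated as converting to built-up land."""
    out = grid.copy()
    out[out == 8] = 7
    return out


def stage_synthetic(cfg: PipelineConfig) -> dict:
    """Generate the two-date landscape pair, area series and indicator series."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = _scenario_spec(cfg)
    rules = _rules(cfg)
    t0 = synthetic.generate_landscape(spec)
    mask = t0.grid == 5  # water is the restricted area in this scenario
    n_changes = int(round(cfg.synthetic.change_fraction * t0.grid.size))
    work = t0.copy()
    work.grid = _fold_unused(work.grid)
    t1 = synthetic.evolve_landscape(work, rules, n_changes,
                                    seed=cfg.child_seed("evolve"), restricted_mask=mask)
    # the area series starts from the realised map composition so the demand
    # forecasts stay consistent with the landscape the CA allocates on
    from dataclasses import replace
    n_cells = t0.grid.size
    realized = tuple((t0.grid == c).sum() / n_cells for c in spec.codes)
    areas = synthetic.generate_area_series(replace(spec, class_fractions=realized),
                                           noise_sd=cfg.synthetic.area_noise_sd)
    socio = synthetic.generate_socioeconomic_series(spec.years, seed=cfg.child_seed("socio"))
    raster.write_raster(work, out / "landuse_t0.asc", seed=cfg.seed, config_hash=cfg.hash())
    raster.write_raster(t1, out / "landuse_t1.asc", seed=cfg.seed, config_hash=cfg.hash())
    np.savetxt(out / "restricted_mask.asc", mask.astype(int), fmt="%d")
    areas.to_csv(out / "area_series.csv", index=False)
    socio.to_csv(out / "socioeconomic_series.csv", index=False)
    legend = pd.DataFrame({"code": list(NAMES), "name": list(NAMES.values())})
    legend.to_csv(out / "legend.csv", index=False)
    _log(cfg, f"synthetic: grid={t0.shape}, {n_changes} cell changes between dates")
    return {"t0": work, "t1": t1, "mask": mask, "areas": areas, "socio": socio,
            "spec": spec, "rules": rules}


def stage_demand(cfg: PipelineConfig, art: dict) -> dict:
    """Grey and Markov forecasts, accuracy grading, model comparison, targets."""
    out = Path(cfg.output_dir)
    areas: pd.DataFrame = art["areas"]
    years = sorted(areas["year"].unique())
    wide = areas.pivot(index="class", columns="year", values="area")
    order = [NAMES[c] for c in CODES if NAMES[c] in wide.index]
    wide = wide.loc[order]

    fits, acc_rows, forecasts = {}, [], {}
    horizon = cfg.demand.horizon
    for cls in wide.index:
        fit = demand.fit_gm11(wide.loc[cls].to_numpy())
        test = demand.posterior_difference_test(fit)
        fits[cls] = fit
        acc_rows.append({"class": cls, "C": test.C, "P": test.P, "level": test.level})
        forecasts[cls] = demand.predict_gm11(fit, horizon)
    acc = pd.DataFrame(acc_rows)
    acc.to_csv(out / "gm_accuracy.csv", index=False)

    step = years[1] - years[0]
    future_years = [years[-1] + step * (i + 1) for i in range(horizon)]
    fc = pd.DataFrame({"class": list(forecasts),
                       **{str(y): [forecasts[c][i] for c in forecasts]
                          for i, y in enumerate(future_years)}})
    fc.to_csv(out / "gm_forecast.csv", index=False)

    # Markov transition frequencies come from the two-date map pair; both
    # models are then compared on the last observed year of the area series
    # (GM in-sample restored value vs a one-step Markov projection from the
    # previous year's composition)
    P = demand.estimate_transition_matrix(art["t0"], art["t1"])
    P.to_csv(out / "transition_matrix.csv")
    cell_km2 = art["t0"].cell_area_ha / 100.0
    order_codes = [c for c in CODES if NAMES[c] in wide.index]
    actual_last = np.array([wide.loc[NAMES[c], years[-1]] for c in order_codes])
    prev = np.zeros(len(CODES))
    for i, c in enumerate(CODES):
        if NAMES[c] in wide.index:
            prev[i] = wide.loc[NAMES[c], years[-2]]
    markov_full = demand.predict_markov(prev, P, steps=1)
    markov_pred = np.array([markov_full[c - 1] for c in order_codes])
    gm_last = np.array([fits[NAMES[c]].fitted[-1] for c in order_codes])
    comparison = demand.compare_models(gm_last, markov_pred, actual_last,
                                       labels=[NAMES[c] for c in order_codes])
    comparison.to_csv(out / "model_comparison.csv", index=False)

    policy = demand.DemandPolicy(
        fold_unused_into_built_up=cfg.demand.fold_unused_into_built_up,
        protection_floor_km2=cfg.demand.protection_floor_km2)
    name_to_code = {v: k for k, v in NAMES.items()}
    # demand is anchored to the base map: each class's allocated count scales
    # by its forecast growth ratio relative to the last observed year, so the
    # targets stay attainable on the landscape the CA starts from
    last_year = years[-1]
    fc_area = {}
    for cls, fc_vals in forecasts.items():
        code = name_to_code[cls]
        observed = wide.loc[cls, last_year]
        ratio = fc_vals[0] / observed if observed > 0 else 1.0
        fc_area[code] = art["t1"].class_counts().get(code, 0) * cell_km2 * ratio
    if all(v == 0 for v in fc_area.values()):
        raise demand.DemandError("empty base-map composition")
    targets = demand.build_demand(fc_area, art["t0"].cell_area_ha,
                                  art["t0"].grid.size, policy)
    pd.Series(targets).rename("cells").to_csv(out / "demand_targets.csv",
                                              index_label="class_code")
    _log(cfg, f"demand: selected={comparison.attrs['selected']}, "
              f"levels={dict(zip(acc['class'], acc['level']))}")
    return {"targets": targets, "comparison": comparison, "accuracy": acc,
            "transition_matrix": P, "forecast": fc}


def stage_suitability(cfg: PipelineConfig, art: dict) -> dict:
    """Normalize factors, screen them per class, train the suitability net."""
    out = Path(cfg.output_dir)
    t1 = art["t1"]
    factors = synthetic.generate_driving_factors(t1, seed=cfg.child_seed("factors"))
    norm = suitability.normalize_stack(factors)
    n = max(int(round(cfg.ann.sample_fraction * t1.grid.size)), 200)
    train = suitability.sample_training(t1, norm, n,
                                        strategy=cfg.ann.sampling_strategy,
                                        seed=cfg.child_seed("sampling"))
    model = suitability.train_suitability_ann(train, hidden_units=cfg.ann.hidden_units,
                                              epochs=cfg.ann.epochs,
                                              seed=cfg.child_seed("ann"))
    suit = suitability.predict_suitability(model, norm, all_codes=CODES[:7])
    screen_rows = []
    for code in CODES[:7]:
        if (t1.grid == code).any():
            res = suitability.screen_factors_logistic(t1, norm, code,
                                                      seed=cfg.child_seed("screen"))
            screen_rows.append({"class": NAMES[code], "intercept": res.intercept,
                                "roc_value": res.roc_auc, "usable": res.usable})
    screen = pd.DataFrame(screen_rows)
    screen.to_csv(out / "factor_screening.csv", index=False)
    raster.write_stack(norm, out / "factors", seed=cfg.seed, config_hash=cfg.hash())
    _log(cfg, f"suitability: trained on {n} cells, "
              f"min ROC={screen['roc_value'].min():.3f}")
    return {"suit": suit, "screen": screen, "model": model, "factors": norm}


def _ca_params(cfg: PipelineConfig, stage: str) -> ca.CAParams:
    return ca.CAParams(neighborhood_size=cfg.ca.neighborhood_size,
                       max_iterations=cfg.ca.max_iterations,
                       demand_tolerance=cfg.ca.demand_tolerance,
                       inertia_floor=cfg.ca.inertia_floor,
                       seed=cfg.child_seed(stage),
                       candidate_mode=cfg.ca.candidate_mode)


def _clamp_frozen(targets: dict[int, int], grid: np.ndarray,
                  mask: np.ndarray) -> dict[int, int]:
    """Raise targets of frozen classes to their frozen cell count.

    Frozen cells cannot leave their class, so a forecast that noses slightly
    below the frozen count is unattainable; the deficit is taken from the
    class with the largest slack so the totals still sum to the grid size.
    """
    targets = dict(targets)
    for c in list(targets):
        frozen_c = int(((grid == c) & mask).sum())
        if targets[c] < frozen_c:
            need = frozen_c - targets[c]
            donor = max(targets, key=lambda j: targets[j] - int(((grid == j) & mask).sum()))
            targets[donor] -= need
            targets[c] = frozen_c
    return targets


def stage_allocate(cfg: PipelineConfig, art: dict) -> dict:
    """Validation run (t0 -> t1 composition) and future allocation."""
    out = Path(cfg.output_dir)
    rules, mask = art["rules"], art["mask"]
    suit = art["suit"]
    art["targets"] = _clamp_frozen(art["targets"], art["t1"].grid, mask)
    # validation: reallocate from t0 toward the actual t1 composition
    t1_counts = {c: art["t1"].class_counts()[c] for c in CODES[:7]}
    sim_t1, log_v = ca.run_allocation(art["t0"], suit, rules, mask, t1_counts,
                                      _ca_params(cfg, "ca"))
    raster.write_raster(sim_t1, out / "landuse_t1_simulated.asc", seed=cfg.seed,
                        config_hash=cfg.hash())
    log_v.to_csv(out / "allocation_log_validation.csv", index=False)
    # future: allocate the forecast demand starting from t1
    future, log_f = ca.run_allocation(art["t1"], suit, rules, mask, art["targets"],
                                      _ca_params(cfg, "ca"))
    raster.write_raster(future, out / "landuse_future.asc", seed=cfg.seed,
                        config_hash=cfg.hash())
    log_f.to_csv(out / "allocation_log_future.csv", index=False)
    _log(cfg, f"allocate: validation sweeps={log_v['sweep'].max() if len(log_v) else 0}, "
              f"future sweeps={log_f['sweep'].max() if len(log_f) else 0}")
    return {"sim_t1": sim_t1, "future": future}


def stage_assess(cfg: PipelineConfig, art: dict) -> dict:
    """1%-sample confusion matrix of the validation map against the truth."""
    out = Path(cfg.output_dir)
    rng = np.random.default_rng(cfg.child_seed("assess"))
    idx = ca.sample_cells(art["t1"], 0.01, rng)
    cm = ca.assess_accuracy(art["t1"].grid.ravel()[idx],
                            art["sim_t1"].grid.ravel()[idx])
    cm_full = ca.assess_accuracy(art["t1"].grid.ravel(), art["sim_t1"].grid.ravel())
    table = cm.counts.copy()
    table["total"] = table.sum(axis=1)
    table["users_accuracy"] = cm.users_accuracy
    table.to_csv(out / "confusion_matrix.csv")
    summary = pd.DataFrame([{"overall_accuracy_pct": cm.overall_accuracy * 100,
                             "kappa": cm.kappa, "n_sampled": cm.n,
                             "overall_accuracy_full_pct": cm_full.overall_accuracy * 100,
                             "kappa_full": cm_full.kappa}])
    summary.to_csv(out / "assessment_summary.csv", index=False)
    _log(cfg, f"assess: OA={cm.overall_accuracy * 100:.2f}% kappa={cm.kappa:.4f} "
              f"(n={cm.n})")
    return {"confusion": cm, "confusion_full": cm_full}


def stage_esv(cfg: PipelineConfig, art: dict) -> dict:
    """Base + revised valuation per year and the trend report."""
    out = Path(cfg.output_dir)
    vc = esv.load_coefficients()
    areas: pd.DataFrame = art["areas"]
    socio: pd.DataFrame = art["socio"]
    results, audit_rows = {}, []
    for year in sorted(areas["year"].unique()):
        a = areas[areas["year"] == year].set_index("class")["area"].to_dict()
        reg = socio[(socio["year"] == year) & (socio["region"] == "regional")].iloc[0].to_dict()
        nat = socio[(socio["year"] == year) & (socio["region"] == "national")].iloc[0].to_dict()
        f = esv.correction_factors(reg, nat)
        results[int(year)] = esv.revised_esv(a, vc, f, unit="km2")
        audit_rows.append({"year": year, "Q": f.Q, "Pw": f.Pw, "Pv": f.Pv,
                           "D": f.D, "S": f.S, "combined": f.combined})
    audit = pd.DataFrame(audit_rows)
    audit.to_csv(out / "correction_factors.csv", index=False)
    report = esv.esv_report(results, unit_divisor=cfg.esv.unit_divisor)
    report.to_csv(out / "esv_report.csv", index=False)
    years = sorted(results)
    total_growth = esv.growth_rate(results[years[0]].total, results[years[-1]].total)
    _log(cfg, f"esv: total growth {years[0]}->{years[-1]} = {total_growth:.2f}%")
    return {"esv_results": results, "report": report, "audit": audit}


def checksums(directory: str | Path) -> pd.DataFrame:
    rows = []
    for p in sorted(Path(directory).rglob("*")):
        if p.is_file() and p.name != "checksums.csv" and p.name != "run.log":
            digest = hashlib.sha256(p.read_bytes()).hexdigest()
            rows.append({"file": str(p.relative_to(directory)), "sha256": digest})
    return pd.DataFrame(rows)


def run_all(cfg: PipelineConfig) -> dict:
    """Execute every stage in framework order and checksum the artifacts."""
    art = stage_synthetic(cfg)
    art.update(stage_demand(cfg, art))
    art.update(stage_suitability(cfg, art))
    art.update(stage_allocate(cfg, art))
    art.update(stage_assess(cfg, art))
    art.update(stage_esv(cfg, art))
    sums = checksums(cfg.output_dir)
    sums.to_csv(Path(cfg.output_dir) / "checksums.csv", index=False)
    art["checksums"] = sums
    _log(cfg, f"run-all complete: {len(sums)} artifacts")
    return art
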