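"""End-to-end orchestration: simulate/load -> preprocess -> featurize ->
train -> infer -> evaluate, under a single master seed.

One seed governs every stochastic stage through derived substreams (jitter,
simulation, split, model), all recorded in the report, so a rerun with the
same config bit-reproduces the report.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classifier as clf
from . import evaluate as ev
from . import features as ft
from . import inference as inf
from . import preprocess as pp
from . import simulate as sim
from .cohort import (
    ConfigurationError,
    jitter_diagnosis_dates,
    read_claims,
    read_groupmap,
    read_registry,
    write_claims,
    write_groupmap,
    write_registry,
)


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str | None = None
    sim: sim.SimConfig | None = None
    registry_path: str | None = None
    claims_path: str | None = None
    groupmap_path: str | None = None
    bin_mode: str = "calendar"
    thresholds: inf.ThresholdConfig = field(default_factory=inf.ThresholdConfig)
    model_params: dict = field(default_factory=lambda: dict(clf.DEFAULT_PARAMS))
    tune_grid: list | None = None  # None skips hyperparameter search
    train_fraction: float = 0.8
    n_folds: int = 5
    include_diagnosis_year: bool = False
    km_threshold: float = 0.5
    write_inputs: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "sim" in raw and raw["sim"] is not None:
            raw["sim"] = sim.SimConfig(**raw["sim"])
        if "thresholds" in raw and raw["thresholds"] is not None:
            raw["thresholds"] = inf.ThresholdConfig(**raw["thresholds"])
        return cls(**raw)


@dataclass
class RunResult:
    report: dict
    panel: pp.MonthPanel
    matrix: ft.FeatureMatrix
    bundle: clf.ModelBundle
    plan: clf.SplitPlan
    sweep: pd.DataFrame
    evaluation: ev.EvaluationReport


def _stage_seeds(master: int) -> dict[str, int]:
    ss = np.random.SeedSequence(master)
    children = ss.spawn(4)
    names = ("sim", "jitter", "split", "model")
    return {
        n: int(c.generate_state(1)[0] % (2**31)) for n, c in zip(names, children)
    }


def run_all(config: RunConfig) -> RunResult:
    """Run the whole pipeline; returns the report and every in-memory artifact."""
    seeds = _stage_seeds(config.seed)

    # --- inputs ---------------------------------------------------------
    if config.sim is not None:
        cohort = sim.simulate_cohort(replace(config.sim, seed=seeds["sim"]))
        records, claims, groupmap = cohort.records, cohort.claims, cohort.groupmap
    else:
        if not (config.registry_path and config.claims_path and config.groupmap_path):
            raise ConfigurationError(
                "either a sim config or registry/claims/groupmap paths are required"
            )
        records = read_registry(config.registry_path).records
        claims_res = read_claims(config.claims_path)
        claims = pd.DataFrame(
            [(e.patient_id, e.day, e.system, e.code, e.code_class)
             for e in claims_res.records],
            columns=["patient_id", "day", "system", "code", "code_class"],
        )
        groupmap = read_groupmap(config.groupmap_path)

    if config.bin_mode == "calendar":
        records = jitter_diagnosis_dates(records, seeds["jitter"])

    # --- preprocessing --------------------------------------------------
    claims = pp.deduplicate_daily(claims)
    claims, dropped_codes = pp.filter_rare_codes(claims)
    windows = pp.assign_valid_windows(records, config.bin_mode)
    eligible, exclusions = pp.filter_eligible(records, windows, claims, config.bin_mode)
    panel = pp.build_month_panel(claims, eligible, windows, groupmap, config.bin_mode)

    # --- features and split ----------------------------------------------
    featurizer = ft.TemporalFeaturizer(config.include_diagnosis_year).fit(panel)
    matrix = featurizer.build(panel)
    plan = clf.split_cohort(
        eligible, config.train_fraction, config.n_folds, seeds["split"]
    )
    train_fm = matrix.rows_for(plan.train_ids)
    test_fm = matrix.rows_for(plan.test_ids)

    # --- model -----------------------------------------------------------
    if config.tune_grid is not None:
        params, tuning = clf.tune(train_fm, plan, config.tune_grid, seeds["model"])
    else:
        params, tuning = dict(config.model_params), None
    bundle = clf.fit(train_fm, params, seeds["model"])
    probs = clf.predict_months(bundle, test_fm)

    # --- person-level inference ------------------------------------------
    series = {}
    for pid, sub in test_fm.index.assign(prob=probs).groupby("patient_id", sort=True):
        sub = sub.sort_values("month_index")
        series[pid] = (sub["month_index"].to_numpy(), sub["prob"].to_numpy())
    sweep = inf.threshold_sweep(series, config.thresholds)

    # --- evaluation -------------------------------------------------------
    truth = {pid: panel.records[pid].sbce for pid in plan.test_ids}
    truth_months = {
        pid: panel.windows[pid].sbce_month
        for pid in plan.test_ids
        if panel.windows[pid].sbce_month is not None
    }
    roc = ev.month_roc(probs, test_fm.y)
    ttable = ev.threshold_table(sweep, truth)
    timing = ev.timing_table(sweep, truth_months)
    km = (
        ev.km_pair(
            truth_months,
            {pid: panel.windows[pid].end_month for pid in truth_months},
            sweep,
            config.km_threshold,
        )
        if truth_months
        else None
    )
    evaluation = ev.EvaluationReport(
        month_auc=roc.auc, threshold_table=ttable, timing_table=timing,
        km=km, roc=roc,
    )

    whole_km = ev.cohort_km(list(panel.records.values()))
    horizon = config.sim.horizon_months if config.sim else 168
    report = {
        "seed": config.seed,
        "stage_seeds": seeds,
        "bin_mode": config.bin_mode,
        "n_input_patients": len(records),
        "n_eligible_patients": len(eligible),
        "exclusions": sorted(
            (e.patient_id, e.reason) for e in exclusions
        ),
        "n_rare_codes_dropped": len(dropped_codes),
        "n_unmapped_claims": panel.n_unmapped_claims,
        "n_train_patients": len(plan.train_ids),
        "n_test_patients": len(plan.test_ids),
        "model_params": {k: (v if not isinstance(v, np.generic) else v.item())
                         for k, v in params.items()},
        "tuning": None if tuning is None else tuning.drop(columns="fold_aucs")
        .to_dict(orient="records"),
        "feature_importance": clf.feature_importance(bundle, top_k=20),
        "cohort_km_cumulative_incidence": ev.cumulative_incidence_at(
            whole_km, horizon
        ),
        **evaluation.to_dict(),
    }

    if config.out_dir:
        _write_artifacts(config, report, sweep, test_fm, probs, exclusions,
                         records, claims, groupmap)
    return RunResult(report, panel, matrix, bundle, plan, sweep, evaluation)


def _write_artifacts(config, report, sweep, test_fm, probs, exclusions,
                     records, claims, groupmap) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)
    test_fm.index.assign(probability=probs).to_csv(out / "probs.csv", index=False)
    sweep.to_csv(out / "persons.csv", index=False)
    with open(out / "exclusions.jsonl", "w") as fh:
        for e in exclusions:
            fh.write(json.dumps({"patient_id": e.patient_id, "reason": e.reason}) + "\n")
    def plain(obj):
        if isinstance(obj, dict):
            return {k: plain(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [plain(v) for v in obj]
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        return obj

    cfg = plain(dataclasses.asdict(config))
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    if config.write_inputs:
        write_registry(records, out / "registry.csv")
        write_claims(claims, out / "claims.csv")
        write_groupmap(groupmap, out / "groupmap.csv")


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
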