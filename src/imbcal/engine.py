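"""Factorial Monte Carlo engine for the imbalance-correction study.

Design (ADEMP-style): for every scenario — a cell of the factorial grid
{training size} x {number of predictors} x {event fraction} — the true
logistic mechanism is calibrated once to a c-statistic of 0.75 and the
target prevalence, a single large test set is drawn, and then each
replicate draws a fresh training set, builds the four training variants
(uncorrected, RUS, ROS, SMOTE), fits standard and ridge logistic models on
each (8 models), adds intercept-recalibrated versions of the 6 corrected
models, and evaluates every model on the scenario's common test set.

Classification is evaluated at the 0.5 threshold for all models, and
additionally at the true event fraction for models trained on uncorrected
data.  Per-cell summaries report the median and quartiles of each metric
over replicates whose fit succeeded; separation and non-convergence events
are tallied separately rather than imputed.

Seeding: every random draw derives from ``numpy.random.SeedSequence`` keyed
on (base_seed, scenario factors, stream), so results are reproducible and
independent of execution order or worker count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from joblib import Parallel, delayed

from . import corrections as corr
from . import metrics as perf
from .datagen import (
    Dataset,
    GeneratorCoefficients,
    ScenarioConfig,
    calibrate_generator,
    generate_dataset,
)
from .models import FitError, fit_ridge, fit_slr, recalibrate_intercept

__all__ = [
    "SimulationSummary",
    "CORRECTIONS",
    "MODELS",
    "TEST_SET_STREAM",
    "scenario_rng",
    "run_replicate",
    "run_scenario",
    "run_grid",
    "full_grid",
    "reduced_grid",
    "summarize_to_table",
    "records_to_rows",
    "load_grid_config",
]

logger = logging.getLogger(__name__)

CORRECTIONS = ("none", "rus", "ros", "smote")
MODELS = ("slr", "ridge")

# stream tag for the scenario's single fixed test set (never a replicate id)
TEST_SET_STREAM = 1_000_003

@dataclass
class SimulationSummary:
    """Per-cell medians/quartiles and error tallies for one scenario."""

    config: ScenarioConfig
    coefficients: GeneratorCoefficients
    table: pd.DataFrame           # tidy: cell x metric with median/q1/q3
    n_errors: int
    raw: pd.DataFrame | None = None  # per-replicate rows, if retained


def scenario_rng(config: ScenarioConfig, stream: int) -> np.random.Generator:
    """Deterministic generator for one (scenario, stream) pair.

    ``stream`` is the replicate index, or the test-set tag for the
    scenario's common test set.
    """
    ss = np.random.SeedSequence(
        entropy=(
            int(config.base_seed),
            int(config.n_train),
            int(config.p),
            int(round(config.event_fraction * 100_000)),
            int(stream),
        )
    )
    return np.random.default_rng(ss)


def _apply_correction(
    name: str, data: Dataset, rng: np.random.Generator
) -> Dataset:
    if name == "none":
        return data
    if name == "rus":
        return corr.random_undersample(data, rng)
    if name == "ros":
        return corr.random_oversample(data, rng)
    if name == "smote":
        return corr.smote(data, rng=rng)
    raise ValueError(f"unknown correction {name!r}")


def run_replicate(
    config: ScenarioConfig,
    replicate_id: int,
    coefs: GeneratorCoefficients,
    test_set: Dataset,
    corrections: tuple[str, ...] = CORRECTIONS,
    models: tuple[str, ...] = MODELS,
    recalibrate: bool = True,
) -> list[perf.PerformanceRecord]:
    """One simulation run: train-set draw, corrections, fits, evaluation.

    With the full protocol this yields 14 records per replicate:
    4 training variants x 2 learners, plus intercept-recalibrated versions
    of the 6 corrected models (recalibrated on the original, imbalanced
    training data).  Fit failures are recorded in the ``meta`` of an
    otherwise-NaN record; the remaining models still run.
    """
    rng = scenario_rng(config, replicate_id)
    train = generate_dataset(config.n_train, coefs, rng)
    if train.outcome.min() == train.outcome.max():
        # pathological draw: no events (or no nonevents) at all
        return [
            _error_record(config, replicate_id, c, m, False, "single-class train")
            for c in corrections
            for m in models
        ]
    records: list[perf.PerformanceRecord] = []
    for correction in corrections:
        try:
            corrected = _apply_correction(correction, train, rng)
        except corr.CorrectionError as exc:
            for m in models:
                records.append(
                    _error_record(config, replicate_id, correction, m, False, str(exc))
                )
            continue
        # thresholds: 0.5 everywhere; also the true event fraction for
        # models trained on uncorrected data
        if correction == "none":
            thresholds = (0.5, config.event_fraction)
        else:
            thresholds = (0.5,)
        for model_name in models:
            try:
                if model_name == "slr":
                    model = fit_slr(corrected)
                else:
                    model = fit_ridge(corrected, rng=rng)
            except (FitError, np.linalg.LinAlgError) as exc:
                records.append(
                    _error_record(
                        config, replicate_id, correction, model_name, False, str(exc)
                    )
                )
                if correction != "none" and recalibrate:
                    records.append(
                        _error_record(
                            config, replicate_id, correction, model_name, True, str(exc)
                        )
                    )
                continue
            probs = model.predict(test_set.predictors)
            rec = perf.evaluate(
                probs,
                test_set.outcome,
                thresholds=thresholds,
                meta=_meta(config, replicate_id, correction, model_name, False),
            )
            rec.meta["converged"] = model.converged
            rec.meta["separation"] = model.separation_detected
            rec.meta["lambda"] = model.lambda_
            records.append(rec)
            if correction != "none" and recalibrate:
                recal = recalibrate_intercept(model, train)
                probs_r = recal.predict(test_set.predictors)
                rec_r = perf.evaluate(
                    probs_r,
                    test_set.outcome,
                    thresholds=(0.5,),
                    meta=_meta(config, replicate_id, correction, model_name, True),
                )
                rec_r.meta["converged"] = model.converged
                rec_r.meta["separation"] = model.separation_detected
                rec_r.meta["lambda"] = model.lambda_
                records.append(rec_r)
    return records


def _meta(config, replicate_id, correction, model_name, recalibrated) -> dict:
    return {
        "n_train": config.n_train,
        "p": config.p,
        "event_fraction": config.event_fraction,
        "replicate": replicate_id,
        "correction": correction,
        "model": model_name,
        "recalibrated": recalibrated,
        "error": "",
    }


def _error_record(
    config, replicate_id, correction, model_name, recalibrated, message
) -> perf.PerformanceRecord:
    meta = _meta(config, replicate_id, correction, model_name, recalibrated)
    meta["error"] = message or "fit failure"
    meta["converged"] = False
    meta["separation"] = False
    meta["lambda"] = float("nan")
    return perf.PerformanceRecord(
        auroc=float("nan"),
        cal_intercept=float("nan"),
        cal_slope=float("nan"),
        cal_slope_intercept=float("nan"),
        thresholds={},
        meta=meta,
    )


def records_to_rows(records: list[perf.PerformanceRecord]) -> pd.DataFrame:
    """Flatten performance records into one tidy row per record.

    Threshold-specific metrics appear twice: at the default 0.5 threshold
    (suffix ``_t50``) and, where evaluated, at the true event fraction
    (suffix ``_tef``).
    """
    rows = []
    for rec in records:
        row = dict(rec.meta)
        row["auroc"] = rec.auroc
        row["cal_intercept"] = rec.cal_intercept
        row["cal_slope"] = rec.cal_slope
        for t, tm in rec.thresholds.items():
            suffix = "_t50" if t == 0.5 else "_tef"
            row[f"accuracy{suffix}"] = tm.accuracy
            row[f"sensitivity{suffix}"] = tm.sensitivity
            row[f"specificity{suffix}"] = tm.specificity
            row[f"net_benefit{suffix}"] = tm.net_benefit
        rows.append(row)
    return pd.DataFrame(rows)


def _summarize_rows(rows: pd.DataFrame, config: ScenarioConfig) -> pd.DataFrame:
    """Per-cell median/quartile table over successful replicates."""
    metric_cols = [
        c
        for c in rows.columns
        if c.split("_t50")[0].split("_tef")[0]
        in {"auroc", "cal_intercept", "cal_slope", "accuracy",
            "sensitivity", "specificity", "net_benefit"}
    ]
    failed = (rows["error"] != "") | (~rows["converged"].astype(bool))
    out = []
    for (correction, model, recal), grp in rows.groupby(
        ["correction", "model", "recalibrated"], sort=True
    ):
        ok = grp[~failed.loc[grp.index]]
        n_err = int(failed.loc[grp.index].sum())
        n_sep = int(grp["separation"].astype(bool).sum())
        for metric in metric_cols:
            vals = ok[metric].dropna()
            out.append(
                {
                    "n_train": config.n_train,
                    "p": config.p,
                    "event_fraction": config.event_fraction,
                    "correction": correction,
                    "model": model,
                    "recalibrated": recal,
                    "metric": metric,
                    "median": vals.median() if len(vals) else float("nan"),
                    "q1": vals.quantile(0.25) if len(vals) else float("nan"),
                    "q3": vals.quantile(0.75) if len(vals) else float("nan"),
                    "n_ok": int(len(vals)),
                    "n_errors": n_err,
                    "n_separation": n_sep,
                }
            )
    return pd.DataFrame(out)


def run_scenario(
    config: ScenarioConfig,
    corrections: tuple[str, ...] = CORRECTIONS,
    models: tuple[str, ...] = MODELS,
    recalibrate: bool = True,
    keep_raw: bool = False,
) -> SimulationSummary:
    """Run all replicates of one scenario and summarize per cell.

    The generator coefficients are calibrated deterministically; all
    replicates share a single test set drawn once from the same mechanism.
    """
    coefs = calibrate_generator(
        config.p, config.event_fraction, config.target_cstat
    )
    # common test set, conditioned on its expected event count so that one
    # finite draw does not shift every calibration summary of the cell
    test_set = generate_dataset(
        config.n_test,
        coefs,
        scenario_rng(config, TEST_SET_STREAM),
        exact_event_count=True,
    )
    all_records: list[perf.PerformanceRecord] = []
    for rep in range(config.n_reps):
        all_records.extend(
            run_replicate(
                config,
                rep,
                coefs,
                test_set,
                corrections=corrections,
                models=models,
                recalibrate=recalibrate,
            )
        )
    rows = records_to_rows(all_records)
    table = _summarize_rows(rows, config)
    n_errors = int((rows["error"] != "").sum())
    return SimulationSummary(
        config=config,
        coefficients=coefs,
        table=table,
        n_errors=n_errors,
        raw=rows if keep_raw else None,
    )


def full_grid(
    base_seed: int = 0, n_reps: int = 200, n_test: int = 100_000
) -> list[ScenarioConfig]:
    """The full factorial grid: {2500, 5000} x {3, 6, 12, 24} x {0.3, 0.1, 0.01}."""
    return [
        ScenarioConfig(
            n_train=n, p=p, event_fraction=ef,
            n_reps=n_reps, n_test=n_test, base_seed=base_seed,
        )
        for n in (2500, 5000)
        for p in (3, 6, 12, 24)
        for ef in (0.3, 0.1, 0.01)
    ]


def reduced_grid(
    base_seed: int = 0, n_reps: int = 200, n_test: int = 50_000
) -> list[ScenarioConfig]:
    """The reduced grid used for desk-scale checks: p restricted to {3, 24}."""
    return [
        ScenarioConfig(
            n_train=n, p=p, event_fraction=ef,
            n_reps=n_reps, n_test=n_test, base_seed=base_seed,
        )
        for n in (2500, 5000)
        for p in (3, 24)
        for ef in (0.3, 0.1, 0.01)
    ]


def run_reduced_study(
    base_seed: int = 0,
    n_reps: int = 200,
    n_test: int = 50_000,
    progress: bool = False,
) -> list[SimulationSummary]:
    """The desk-scale preset of the study: reduced grid, reduced replication.

    The n_train=5000, p=3 cells run the full 14-model protocol (all four
    training variants, both learners, recalibration); the remaining cells
    fit only the uncorrected-data models, which is what the headline
    uncorrected-calibration summaries need.  Runs in tens of minutes on one
    CPU rather than the hours-scale full factorial at 2,000 replicates.
    """
    summaries = []
    for cfg in reduced_grid(base_seed, n_reps, n_test):
        full = cfg.n_train == 5000 and cfg.p == 3
        if progress:
            print(f"  running scenario {cfg.label} "
                  f"({'full' if full else 'uncorrected-only'}) ...", flush=True)
        summaries.append(
            run_scenario(cfg) if full else run_scenario(cfg, corrections=("none",))
        )
    return summaries


def run_grid(
    configs: list[ScenarioConfig],
    out_dir: str | Path | None = None,
    n_jobs: int = 1,
    **scenario_kwargs,
) -> list[SimulationSummary]:
    """Run a list of scenarios, optionally in parallel and resumably.

    With ``out_dir`` set, each scenario's summary table is written to
    ``<label>.csv`` as it completes and scenarios with an existing file are
    skipped (their tables are loaded instead), so interrupted grids resume.
    Parallelism is scenario-level only; replicate seeds are pre-determined,
    so results do not depend on ``n_jobs``.
    """
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)

    def one(cfg: ScenarioConfig) -> SimulationSummary:
        if out_path is not None:
            f = out_path / f"{cfg.label}.csv"
            if f.exists():
                logger.info("resuming: %s already done", cfg.label)
                coefs = calibrate_generator(cfg.p, cfg.event_fraction, cfg.target_cstat)
                table = pd.read_csv(f)
                return SimulationSummary(
                    config=cfg,
                    coefficients=coefs,
                    table=table,
                    n_errors=int(table["n_errors"].max()) if len(table) else 0,
                )
        summary = run_scenario(cfg, **scenario_kwargs)
        if out_path is not None:
            summary.table.to_csv(out_path / f"{cfg.label}.csv", index=False)
        return summary

    if n_jobs == 1:
        return [one(cfg) for cfg in configs]
    return Parallel(n_jobs=n_jobs)(delayed(one)(cfg) for cfg in configs)


def summarize_to_table(summaries: list[SimulationSummary]) -> pd.DataFrame:
    """Stack per-scenario summaries into one long-format results table."""
    if not summaries:
        raise ValueError("at least one summary required")
    return pd.concat([s.table for s in summaries], ignore_index=True)


def load_grid_config(path: str | Path, base_seed: int = 0) -> list[ScenarioConfig]:
    """Build a scenario list from a YAML/JSON grid description.

    The file holds lists under ``n_train``, ``p``, ``event_fraction`` and
    scalars ``n_reps`` / ``n_test``; the cross product defines the grid.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return [
        ScenarioConfig(
            n_train=int(n),
            p=int(p),
            event_fraction=float(ef),
            n_reps=int(cfg.get("n_reps", 200)),
            n_test=int(cfg.get("n_test", 100_000)),
            base_seed=int(cfg.get("base_seed", base_seed)),
        )
        for n in cfg["n_train"]
        for p in cfg["p"]
        for ef in cfg["event_fraction"]
    ]
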