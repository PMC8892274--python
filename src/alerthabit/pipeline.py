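"""End-to-end orchestration: ingest -> habit -> features -> descriptives ->
correlations -> regressions -> report bundle with a hashed manifest."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import correlation_matrix
from .descriptives import plot_figures, summarize_log, time_by_exposure
from .event_log import EventLog, read_event_log, validate, write_event_log
from .features import assemble_analysis_table
from .habit_model import DEFAULT_ALPHAS, habit_column
from .regression import (
    EstimationError,
    ModelSpec,
    fit_by_rank,
    fit_logit,
    fit_processing_time,
    standardized_odds_effect,
)
from .simulate import SimulationConfig, ground_truth_report, simulate_log

log = logging.getLogger("alerthabit")

OUTCOMES = ("dismiss", "dismiss1", "dismiss2", "dismiss3")


@dataclass
class RunConfig:
    """Configuration of a pipeline run.

    Exactly one of ``input_path`` (an event-log CSV) or ``simulation``
    (a SimulationConfig) provides the input.
    """

    output_dir: str | Path = "alerthabit_out"
    input_path: str | Path | None = None
    simulation: SimulationConfig | None = None
    alphas: tuple = DEFAULT_ALPHAS
    outcomes: tuple = OUTCOMES
    estimators: tuple = ("fixed_effects",)
    by_rank: bool = False
    plots: bool = False
    seed: int = 0

    def validate(self) -> None:
        if (self.input_path is None) == (self.simulation is None):
            raise ValueError("provide exactly one of input_path or simulation")
        if not self.alphas or any(not 0 < a < 1 for a in self.alphas):
            raise ValueError("alphas must be non-empty values in (0,1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", None)
        cfg = cls(**{k: v for k, v in raw.items() if k in cls.__dataclass_fields__})
        if sim is not None:
            cfg.simulation = SimulationConfig(**sim)
        if "alphas" in raw:
            cfg.alphas = tuple(raw["alphas"])
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage; returns the manifest (also written to the bundle).

    A stage failure aborts with the stage name and cause; files written so
    far are flagged as partial in the manifest on disk.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    import numpy
    import scipy
    import statsmodels

    manifest: dict = {
        "version": __version__,
        "library_versions": {
            "numpy": numpy.__version__,
            "pandas": pd.__version__,
            "scipy": scipy.__version__,
            "statsmodels": statsmodels.__version__,
        },
        "seed": config.seed,
        "stages": {},
        "files": {},
        "partial": True,
    }
    written: list[Path] = []
    current_stage = "setup"

    def emit(name: str, path: Path) -> None:
        written.append(path)
        manifest["files"][str(path.relative_to(outdir))] = _sha256(path)

    def stage(name: str):
        nonlocal current_stage
        current_stage = name
        log.info("stage %s", name)
        manifest["stages"][name] = {"started": time.time()}

    def done(name: str, **info) -> None:
        manifest["stages"][name]["seconds"] = round(
            time.time() - manifest["stages"][name].pop("started"), 3
        )
        manifest["stages"][name].update(info)

    try:
        stage("ingest")
        if config.simulation is not None:
            event_log, truth = simulate_log(config.simulation)
            p = write_event_log(event_log, outdir / "event_log.csv")
            emit("event_log", p)
            tp = truth.to_json(outdir / "ground_truth.json")
            emit("ground_truth", tp)
            (outdir / "ground_truth_summary.json").write_text(
                json.dumps(ground_truth_report(truth), indent=2))
            emit("ground_truth_summary", outdir / "ground_truth_summary.json")
        else:
            event_log = read_event_log(config.input_path)
        report = validate(event_log)
        if not report.valid:
            raise ValueError(f"input log invalid: {report}")
        done("ingest", n_events=len(event_log))

        stage("features")
        table = assemble_analysis_table(event_log, config.alphas)
        table_path = outdir / "analysis_table.csv"
        table.to_csv(table_path, index=False)
        emit("analysis_table", table_path)
        done("features", n_rows=len(table))

        stage("descriptives")
        summary = summarize_log(table)
        summary.variables.to_csv(outdir / "summary_table.csv")
        emit("summary_table", outdir / "summary_table.csv")
        (outdir / "summary_percentages.json").write_text(
            json.dumps(summary.rounded(3), indent=2))
        emit("summary_percentages", outdir / "summary_percentages.json")
        tbe = time_by_exposure(table)
        tbe.to_csv(outdir / "time_by_exposure.csv", index=False)
        emit("time_by_exposure", outdir / "time_by_exposure.csv")
        if config.plots:
            for p in plot_figures(table, outdir / "figures", config.alphas):
                emit(p.name, p)
        done("descriptives")

        stage("correlations")
        habit_cols = [habit_column(a) for a in config.alphas]
        corr_vars = [o for o in OUTCOMES if o in table.columns] + habit_cols
        corr = correlation_matrix(table, corr_vars)
        corr.values.to_csv(outdir / "correlations_wide.csv")
        emit("correlations_wide", outdir / "correlations_wide.csv")
        corr.to_long().to_csv(outdir / "correlations_long.csv", index=False)
        emit("correlations_long", outdir / "correlations_long.csv")
        done("correlations")

        # regressions need real covariate variation; count fixtures carry
        # constant clinical covariates and skip the model stages
        has_covariates = (
            table["physician_id"].nunique() > 1
            and table.groupby("physician_id")["dismiss"].nunique().max() > 1
            and any(table[c].nunique() > 1
                    for c in ("patient_age", "length_of_stay", "diagnosis_count"))
        )
        if has_covariates:
            stage("regressions")
            models_dir = outdir / "models"
            models_dir.mkdir(exist_ok=True)
            n_models = 0
            for estimator in config.estimators:
                for outcome in config.outcomes:
                    for hcol in habit_cols:
                        spec = ModelSpec(outcome=outcome, habit=hcol,
                                         estimator=estimator)
                        try:
                            result = fit_logit(table, spec)
                        except (EstimationError, np.linalg.LinAlgError) as exc:
                            log.warning("%s/%s/%s failed: %s",
                                        estimator, outcome, hcol, exc)
                            continue
                        sd = float(table[hcol].std(ddof=1))
                        payload = result.to_dict()
                        if sd > 0:
                            payload["per_sd_effect"] = standardized_odds_effect(
                                result, hcol, sd)
                        fp = models_dir / f"{estimator}_{outcome}_{hcol}.json"
                        fp.write_text(json.dumps(payload, indent=2))
                        emit(fp.name, fp)
                        n_models += 1
            if config.by_rank:
                spec = ModelSpec(outcome="dismiss", habit=habit_cols[min(1, len(habit_cols) - 1)])
                for outcome in config.outcomes:
                    by_rank = fit_by_rank(table, ModelSpec(outcome=outcome,
                                                           habit=spec.habit))
                    fp = models_dir / f"by_rank_{outcome}.json"
                    fp.write_text(json.dumps(
                        {r: m.to_dict() for r, m in by_rank.items()}, indent=2))
                    emit(fp.name, fp)
            done("regressions", n_models=n_models)

            stage("processing_time_models")
            pt_results = {}
            for estimator in ("fixed_effects", "random_effects", "pooled"):
                try:
                    res = fit_processing_time(table, estimator=estimator,
                                              habit=habit_cols[min(1, len(habit_cols) - 1)])
                    pt_results[estimator] = res.to_dict()
                except EstimationError as exc:
                    pt_results[estimator] = {"error": str(exc)}
            fp = outdir / "processing_time_models.json"
            fp.write_text(json.dumps(pt_results, indent=2))
            emit(fp.name, fp)
            done("processing_time_models")
        else:
            log.info("regressions skipped: no within-physician outcome "
                     "variation (count-fixture input)")
            manifest["stages"]["regressions"] = {"skipped": "no covariates"}

        manifest["partial"] = False
    except Exception as exc:
        manifest["error"] = {"stage": current_stage, "cause": repr(exc)}
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise RuntimeError(f"pipeline failed at stage {current_stage!r}: {exc}") from exc

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
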