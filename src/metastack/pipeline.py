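"""End-to-end pipeline: simulate -> impute -> stack -> meta-fit ->
evaluate -> importance, with a run manifest capturing every protocol
constant and seed so a run is exactly reproducible.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from ._rng import stream_seed
from .cohort import CohortTable, GeneratorConfig, simulate_cohort
from .exceptions import InvalidArgument
from .imputation import outcome_availability_mask
from .importance import base_learner_importance, meta_importance
from .learners import MLPHyper, PreprocessSpec
from .protocols import (evaluate_base_learners, evaluate_meta_learners, reports_frame)
from .stacking import default_base_learners, develop_stacked_models, make_bootstrap_plans


@dataclass
class RunConfig:
    """Pipeline constants; the defaults instantiate the full protocol:
    m=10 imputations x B=20 bootstraps (200 base fits per learner), 4-knot
    splines on the 3 continuous predictors, (256,256,256) MLPs, meta-
    learners on the 2 averaged prediction columns, R=200 meta bootstrap
    replicates, importance over 10 models x 100 shuffles."""

    seed: int = 0
    n: int = 2000                      # simulated cohort size (when simulating)
    m: int = 10
    B: int = 20
    R: int = 200
    knots: int = 4
    mlp_width: int = 256
    mlp_depth: int = 3
    n_importance_models: int = 10
    n_shuffles: int = 100
    preprocess: str = "none"
    tasks: tuple[str, ...] = ("continuous", "binary")
    imputation_cycles: int = 5
    generator: GeneratorConfig | None = None
    out_dir: str | None = None

    def validate(self) -> None:
        for name in ("m", "B", "R", "knots", "mlp_width", "mlp_depth",
                     "n_importance_models", "n_shuffles"):
            if getattr(self, name) < 1:
                raise InvalidArgument(f"{name} must be positive")
        for t in self.tasks:
            if t not in ("continuous", "binary"):
                raise InvalidArgument(f"unknown task {t!r}")

    @property
    def mlp_hyper(self) -> MLPHyper:
        return MLPHyper(width=self.mlp_width, depth=self.mlp_depth)

    @property
    def base_specs(self):
        return default_base_learners(mlp_hyper=self.mlp_hyper,
                                     preprocess=PreprocessSpec(self.preprocess))


def build_manifest(config: RunConfig, table: CohortTable) -> dict:
    """Resolve the run plan into a manifest without fitting anything.

    Instantiates the bootstrap plans and the learner registry so that every
    protocol constant in the manifest reflects what a run would execute."""
    config.validate()
    schema = table.schema
    specs = config.base_specs
    per_task = {}
    for task in config.tasks:
        elig = outcome_availability_mask(table, task)
        n_elig = int(elig.size)
        plans = make_bootstrap_plans(max(n_elig, 1), config.m, config.B,
                                     stream_seed(config.seed, "plans"))
        per_task[task] = {
            "n_eligible": n_elig,
            "n_plans": len(plans),
            "n_base_fits": len(plans) * len(specs),
        }
    regions = sorted(set(table.data[schema.region]))
    return {
        "seed": config.seed,
        "n_patients": table.n,
        "n_predictors": len(schema.predictors),
        "m_imputations": config.m,
        "B_bootstraps": config.B,
        "n_plans": config.m * config.B,
        "R_meta_bootstrap": config.R,
        "spline_knots": config.knots,
        "spline_predictors": schema.spline_predictors,
        "mlp_hidden_layers": list(config.mlp_hyper.hidden_layer_sizes),
        "base_learners": [s.name for s in specs],
        "meta_input_columns": len(specs),
        "importance_models": config.n_importance_models,
        "importance_shuffles": config.n_shuffles,
        "preprocess": config.preprocess,
        "regions": regions,
        "n_regions": len(regions),
        "tasks": list(config.tasks),
        "per_task": per_task,
        "stage_seeds": {s: stream_seed(config.seed, s)
                        for s in ("impute", "plans", "oob", "meta", "evaluate", "importance")},
    }


@dataclass
class PipelineResult:
    manifest: dict
    reports: pd.DataFrame
    importance: pd.DataFrame
    models: dict          # task -> StackedModel
    cohort: CohortTable


def run_pipeline(config: RunConfig, table: CohortTable | None = None) -> PipelineResult:
    """Execute the full pipeline; rerunning with the same config and cohort
    reproduces every number exactly."""
    config.validate()
    if table is None:
        gen = config.generator or GeneratorConfig(n=config.n, seed=stream_seed(config.seed, "simulate"))
        table, _, _ = simulate_cohort(gen)
    manifest = build_manifest(config, table)
    all_reports, all_importance, models = [], [], {}
    for task in config.tasks:
        model = develop_stacked_models(
            table, task, m=config.m, B=config.B, seed=config.seed,
            specs=config.base_specs, meta_hyper=config.mlp_hyper,
            cycles=config.imputation_cycles,
        )
        models[task] = model
        all_reports += evaluate_base_learners(model.oob, task)
        all_reports += evaluate_meta_learners(
            model.features, model.y_meta, task, R=config.R,
            seed=stream_seed(config.seed, "evaluate", task), mlp_hyper=config.mlp_hyper)
        imp = base_learner_importance(
            model.oob, model.stack, task, n_models=config.n_importance_models,
            n_shuffles=config.n_shuffles, seed=stream_seed(config.seed, "importance", task))
        imp.insert(0, "task", task)
        metric = "MAE" if task == "continuous" else "AUC"
        mimp = meta_importance({"meta_linear": model.meta_linear, "meta_mlp": model.meta_mlp},
                               model.features, model.y_meta, metric,
                               n_shuffles=config.n_shuffles,
                               seed=stream_seed(config.seed, "meta-importance", task))
        mimp.insert(0, "task", task)
        all_importance += [imp, mimp]
    reports = reports_frame(all_reports)
    importance = pd.concat(all_importance, ignore_index=True)
    result = PipelineResult(manifest, reports, importance, models, table)
    if config.out_dir is not None:
        _write_bundle(result, config.out_dir)
    return result


def _write_bundle(result: PipelineResult, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "manifest.json").write_text(json.dumps(result.manifest, indent=2, default=str))
    result.reports.to_csv(out / "metric_reports.csv", index=False)
    result.importance.to_csv(out / "importance.csv", index=False)
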