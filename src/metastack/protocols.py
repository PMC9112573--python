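"""Evaluation protocols.

Base-learners are summarized by averaging the m x B per-replicate
out-of-bag metric values (point estimate) with 2.5th-97.5th percentile
bootstrap intervals.  Meta-learner uncertainty comes from a row-resampling
bootstrap of the meta-feature table: each resample refits both
meta-learners and scores them on the resample's out-of-bag complement.
Transportability is assessed by internal-external cross-validation: leave
one data-collection region out, develop everything (imputation models,
knots, scalers, base and meta learners) on the remaining regions, score
all four models on the held-out region, cycle through all regions and
average.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._rng import stream, stream_seed
from .cohort import CohortTable
from .exceptions import InvalidArgument, ProtocolError, UndefinedAUC
from .imputation import outcome_availability_mask
from .learners import MLPHyper
from .metrics import auc, calibration_in_the_large, mae, percentile_ci
from .stacking import (LearnerSpec, MetaFeatures, OOBResult, develop_stacked_models,
                       fit_meta_linear, fit_meta_mlp)

MODEL_ORDER = ["ridge", "mlp", "meta_linear", "meta_mlp"]


@dataclass(frozen=True)
class MetricReport:
    model: str
    task: str
    metric: str
    point: float
    ci: tuple[float, float]
    n_replicates: int

    def as_row(self) -> dict:
        return {"model": self.model, "task": self.task, "metric": self.metric,
                "estimate": self.point, "ci_low": self.ci[0], "ci_high": self.ci[1],
                "n_replicates": self.n_replicates}


def reports_frame(reports: list[MetricReport]) -> pd.DataFrame:
    return pd.DataFrame([r.as_row() for r in reports])


def evaluate_base_learners(oob: OOBResult, task: str) -> list[MetricReport]:
    """Point = mean of the m x B per-plan out-of-bag metric values; CI =
    percentile interval of those values."""
    pm = oob.plan_metrics
    if pm is None or len(pm) == 0:
        raise ProtocolError("out-of-bag generation was run without metric logging")
    metric_cols = [c for c in pm.columns if c not in ("imputation", "replicate", "learner")]
    reports = []
    for learner, grp in pm.groupby("learner", sort=False):
        for mc in metric_cols:
            vals = grp[mc].to_numpy(dtype=float)
            point = float(np.nanmean(vals))
            reports.append(MetricReport(learner, task, mc, point,
                                        percentile_ci(vals), len(vals)))
    return reports


def _score(task: str, y: np.ndarray, pred: np.ndarray) -> dict[str, float]:
    if task == "continuous":
        return {"MAE": mae(y, pred).value}
    out = {}
    try:
        out["AUC"] = auc(y, pred).value
    except UndefinedAUC:
        out["AUC"] = np.nan
    out["calib_diff"] = calibration_in_the_large(y, np.clip(pred, 0, 1))[2]
    return out


def evaluate_meta_learners(features: MetaFeatures, y, task: str, R: int = 200,
                           seed: int = 0, mlp_hyper: MLPHyper = MLPHyper()) -> list[MetricReport]:
    """Row-resampling bootstrap of the meta-feature table: refit each
    meta-learner on the resample, score on the out-of-bag complement."""
    if R < 2:
        raise InvalidArgument("R must be >= 2")
    y = np.asarray(y, dtype=float)
    X = features.frame
    n = len(X)
    rows: dict[str, list[dict]] = {"meta_linear": [], "meta_mlp": []}
    for r in range(R):
        rng = stream(seed, "meta-boot", r)
        idx = rng.integers(0, n, size=n)
        oob_idx = np.setdiff1d(np.arange(n), idx)
        if oob_idx.size == 0 or np.unique(y[idx]).size < 2:
            continue
        Xb, yb = X.iloc[idx], y[idx]
        Xo, yo = X.iloc[oob_idx], y[oob_idx]
        lin = fit_meta_linear(Xb, yb, task)
        mm = fit_meta_mlp(Xb, yb, task, seed=stream_seed(seed, "meta-boot-mlp", r),
                          hyper=mlp_hyper)
        rows["meta_linear"].append(_score(task, yo, lin.predict(Xo)))
        rows["meta_mlp"].append(_score(task, yo, mm.predict(Xo)))
    reports = []
    for model, recs in rows.items():
        frame = pd.DataFrame(recs)
        for mc in frame.columns:
            vals = frame[mc].to_numpy(dtype=float)
            reports.append(MetricReport(model, task, mc, float(np.nanmean(vals)),
                                        percentile_ci(vals), len(vals)))
    return reports


# ---------------------------------------------------------------------------
# Internal-external cross-validation
# ---------------------------------------------------------------------------


@dataclass
class RegionReport:
    """Per-region metrics for every model plus the unweighted across-region
    average (rows with region == 'average')."""

    frame: pd.DataFrame

    def average(self) -> pd.DataFrame:
        return self.frame[self.frame["region"] == "average"]


def develop_fold(train: CohortTable, task: str, m: int, B: int, seed: int,
                 specs: tuple[LearnerSpec, ...] | None = None,
                 meta_hyper: MLPHyper = MLPHyper(), cycles: int = 5):
    """Develop all four models on the training regions of one fold.

    Every frozen quantity — imputation models, spline knots, scalers,
    learner parameters — is estimated from the training table only, so the
    fold's models are invariant to the held-out region's data."""
    return develop_stacked_models(train, task, m=m, B=B, seed=seed, specs=specs,
                                  meta_hyper=meta_hyper, cycles=cycles)


def internal_external_cv(table: CohortTable, task: str, m: int = 10, B: int = 20,
                         seed: int = 0, specs: tuple[LearnerSpec, ...] | None = None,
                         meta_hyper: MLPHyper = MLPHyper(), cycles: int = 5) -> RegionReport:
    """Leave-one-region-out validation over all regions present.

    Each fold develops imputation and all learners on the other regions,
    then imputes the held-out region from the frozen training imputers
    (single seeded draw per copy) and scores all four models on its
    outcome-observed patients.  Regions lacking both outcome classes (binary
    task) are skipped with a warning row."""
    regions = [r for r in table.schema.regions if (table.data[table.schema.region] == r).any()]
    if len(regions) < 2:
        raise InvalidArgument("internal-external validation needs >= 2 regions")
    ycol = table.schema.y_cont if task == "continuous" else table.schema.y_bin
    rows = []
    for fold_i, region in enumerate(regions):
        is_test = (table.data[table.schema.region] == region).to_numpy()
        train = CohortTable(table.data.loc[~is_test].reset_index(drop=True), table.schema)
        test = CohortTable(table.data.loc[is_test].reset_index(drop=True), table.schema)
        y_test = test.data[ycol].to_numpy(dtype=float)
        obs = outcome_availability_mask(test, task)
        if obs.size == 0 or (task == "binary" and np.unique(y_test[obs]).size < 2):
            import warnings

            warnings.warn(f"region {region} lacks both outcome classes; skipped")
            continue
        model = develop_fold(train, task, m, B, stream_seed(seed, "fold", fold_i),
                             specs=specs, meta_hyper=meta_hyper, cycles=cycles)
        preds = model.predict_new(test, seed=stream_seed(seed, "fold-predict", fold_i))
        for name in MODEL_ORDER:
            for metric, val in _score(task, y_test[obs], preds[name][obs]).items():
                rows.append({"region": region, "model": name, "task": task,
                             "metric": metric, "value": val})
    frame = pd.DataFrame(rows)
    avg = (frame.groupby(["model", "task", "metric"], sort=False)["value"]
           .mean().reset_index())
    avg.insert(0, "region", "average")
    return RegionReport(pd.concat([frame, avg], ignore_index=True))
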