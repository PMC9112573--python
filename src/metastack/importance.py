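"""Permutation feature importance.

A predictor's importance is the percent degradation of a test-set metric
when its values are randomly shuffled in the evaluation data while all
other columns stay fixed: for MAE, 100*(MAE_shuffled - MAE_orig)/MAE_orig;
for AUC, 100*(AUC_orig - AUC_shuffled)/AUC_orig — both oriented so larger
means more important.  The default protocol samples 10 already-trained
bootstrap models (without replacement), shuffles each predictor of each
model's own out-of-bag data 100 times, and averages percent changes over
shuffles and then models.  The same machinery, applied to the meta-learner
input columns, measures the relative contribution of each base-learner.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._rng import stream
from .exceptions import InvalidArgument
from .imputation import ImputationStack, outcome_availability_mask
from .metrics import auc, mae
from .stacking import MetaFeatures, ModelRecord, OOBResult


@dataclass(frozen=True)
class ImportanceRecord:
    model: str
    feature: str
    metric: str
    pct_change: float        # mean over shuffles then models; larger = more important
    per_model: tuple[float, ...]
    n_models: int
    n_shuffles: int

    def as_row(self) -> dict:
        return {"model": self.model, "feature": self.feature, "metric": self.metric,
                "pct_change": self.pct_change, "n_models": self.n_models,
                "n_shuffles": self.n_shuffles}


def _metric_fn(metric: str):
    if metric == "MAE":
        return lambda y, p: mae(y, p).value
    if metric == "AUC":
        return lambda y, p: auc(y, p).value
    raise InvalidArgument(f"unsupported importance metric {metric!r}")


def _pct(metric: str, orig: float, shuf: float) -> float:
    if metric == "MAE":
        return 100.0 * (shuf - orig) / orig
    return 100.0 * (orig - shuf) / orig


def permutation_importance(models: list[tuple], feature: str, n_shuffles: int,
                           metric: str, seed: int = 0, model_name: str = "") -> ImportanceRecord:
    """Importance of one raw predictor for a set of fitted base models.

    ``models`` is a list of (learner, eval_df, y_eval) triples, each
    learner paired with its own out-of-sample evaluation set.  Shuffling
    happens on the design-matrix block of the feature, which is equivalent
    to shuffling the raw column and re-applying the frozen transform.
    """
    score = _metric_fn(metric)
    per_model = []
    for mi, (learner, eval_df, y_eval) in enumerate(models):
        if feature not in learner.builder.blocks_:
            raise InvalidArgument(f"unknown feature {feature!r}")
        Z = learner.builder.transform(eval_df)
        orig = score(y_eval, learner.predict_design(Z))
        sl = learner.builder.blocks_[feature]
        block = Z[:, sl].copy()
        rng = stream(seed, "perm", model_name, feature, mi)
        changes = []
        for _ in range(n_shuffles):
            perm = rng.permutation(len(eval_df))
            Z[:, sl] = block[perm]
            changes.append(_pct(metric, orig, score(y_eval, learner.predict_design(Z))))
        Z[:, sl] = block  # restore; eval data never corrupted
        per_model.append(float(np.mean(changes)))
    return ImportanceRecord(model_name, feature, metric, float(np.mean(per_model)),
                            tuple(per_model), len(models), n_shuffles)


def base_learner_importance(oob: OOBResult, stack: ImputationStack, task: str,
                            features: list[str] | None = None, n_models: int = 10,
                            n_shuffles: int = 100, seed: int = 0) -> pd.DataFrame:
    """Default protocol over the trained bootstrap replicates: per learner,
    sample ``n_models`` fitted models uniformly without replacement, shuffle
    each predictor of their own out-of-bag data ``n_shuffles`` times."""
    table0 = stack.datasets[0]
    schema = table0.schema
    metric = "MAE" if task == "continuous" else "AUC"
    eligible = oob.store.positions
    ycol = schema.y_cont if task == "continuous" else schema.y_bin
    y_all = table0.data[ycol].to_numpy(dtype=float)[eligible]
    features = features if features is not None else schema.names
    rows = []
    by_learner: dict[str, list[ModelRecord]] = {}
    for rec in oob.models:
        by_learner.setdefault(rec.learner_name, []).append(rec)
    for lname, recs in by_learner.items():
        rng = stream(seed, "model-sample", lname)
        chosen = [recs[i] for i in rng.choice(len(recs), size=min(n_models, len(recs)),
                                              replace=False)]
        triples = []
        for rec in chosen:
            dfp = stack.datasets[rec.plan.imputation].data.iloc[eligible]
            triples.append((rec.learner, dfp.iloc[rec.plan.oob], y_all[rec.plan.oob]))
        for feat in features:
            rec_ = permutation_importance(triples, feat, n_shuffles, metric,
                                          seed=seed, model_name=lname)
            rows.append(rec_.as_row())
    return pd.DataFrame(rows)


def meta_importance(meta_models: dict[str, object], features: MetaFeatures, y,
                    metric: str, n_shuffles: int = 100, seed: int = 0) -> pd.DataFrame:
    """Importance of each base-learner's prediction column for each
    meta-learner, plus the between-learner importance ratio."""
    cols = features.prediction_columns
    if len(cols) < 2:
        raise InvalidArgument("meta importance needs >= 2 prediction columns")
    score = _metric_fn(metric)
    y = np.asarray(y, dtype=float)
    X = features.frame.to_numpy(dtype=float)
    rows = []
    for mname, model in meta_models.items():
        orig = score(y, model.predict(X))
        pct_by_col = {}
        for ci, col in enumerate(features.frame.columns):
            if col not in cols:
                continue
            rng = stream(seed, "meta-perm", mname, col)
            keep = X[:, ci].copy()
            changes = []
            for _ in range(n_shuffles):
                X[:, ci] = keep[rng.permutation(len(y))]
                changes.append(_pct(metric, orig, score(y, model.predict(X))))
            X[:, ci] = keep
            pct_by_col[col] = float(np.mean(changes))
        ratio = _safe_ratio(pct_by_col)
        for col, pct in pct_by_col.items():
            rows.append({"model": mname, "feature": col, "metric": metric,
                         "pct_change": pct, "importance_ratio": ratio,
                         "n_models": 1, "n_shuffles": n_shuffles})
    return pd.DataFrame(rows)


def _safe_ratio(pct_by_col: dict[str, float]) -> float:
    """Ratio of the larger to the smaller importance (inf-safe)."""
    vals = sorted(pct_by_col.values(), key=abs, reverse=True)
    if len(vals) < 2 or abs(vals[1]) < 1e-12:
        return float("inf")
    return abs(vals[0]) / abs(vals[1])
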