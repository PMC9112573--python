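"""Bootstrap out-of-sample stacking.

The meta-learners must be trained on base-learner predictions that carry
no information leak: a prediction for patient i may only come from a model
whose bootstrap training multiset did not contain i.  For each of the m
imputed datasets, B bootstrap samples of the outcome-observed patients are
drawn (size n, with replacement); each base-learner is fitted on the
bootstrap sample and predicts on its out-of-bag complement.  Predictions
are accumulated per (patient, learner) and averaged across all m x B
replicates into exactly one meta-feature row per patient.  The two
averaged prediction columns (ridge, MLP) are the sole default inputs to
two meta-learners: an unregularized linear/logistic regression, and an
MLP.  Patient covariates can optionally be appended to the meta inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from ._rng import stream, stream_seed
from .cohort import CohortTable
from .exceptions import EmptyMetaFeatures, InvalidArgument
from .imputation import ImputationStack, impute, outcome_availability_mask
from .learners import FittedLearner, MLPHyper, PreprocessSpec, fit_mlp, fit_mlp_array, fit_ridge
from .metrics import auc, calibration_in_the_large, mae
from .exceptions import UndefinedAUC


@dataclass(frozen=True)
class LearnerSpec:
    """Registry entry for one base-learner."""

    name: str
    kind: str  # ridge | mlp
    preprocess: PreprocessSpec = PreprocessSpec()
    penalty: float | str = "cv"      # ridge only
    hyper: MLPHyper = MLPHyper()     # mlp only

    def fit(self, df: pd.DataFrame, y, task: str, schema, seed: int) -> FittedLearner:
        if self.kind == "ridge":
            return fit_ridge(df, y, task, schema, preprocess=self.preprocess,
                             seed=seed, penalty=self.penalty)
        if self.kind == "mlp":
            return fit_mlp(df, y, task, schema, hyper=self.hyper,
                           preprocess=self.preprocess, seed=seed)
        raise InvalidArgument(f"unknown learner kind {self.kind!r}")


def default_base_learners(mlp_hyper: MLPHyper = MLPHyper(),
                          preprocess: PreprocessSpec = PreprocessSpec()) -> tuple[LearnerSpec, ...]:
    """The canonical pair: penalized spline regression + MLP."""
    return (
        LearnerSpec("ridge", "ridge", preprocess=preprocess),
        LearnerSpec("mlp", "mlp", preprocess=preprocess, hyper=mlp_hyper),
    )


# ---------------------------------------------------------------------------
# Bootstrap plans
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BootstrapPlan:
    """One (imputation, replicate) bootstrap: the in-sample multiset and its
    exact out-of-sample complement."""

    imputation: int
    replicate: int
    in_sample: np.ndarray
    oob: np.ndarray


def make_bootstrap_plans(n: int, m: int, B: int, seed: int = 0) -> list[BootstrapPlan]:
    """m*B plans over ``n`` eligible patients; each in-sample multiset has
    size n, drawn uniformly with replacement; deterministic given seed."""
    if n < 1:
        raise InvalidArgument("n must be >= 1")
    if m < 1 or B < 1:
        raise InvalidArgument("m and B must be >= 1")
    plans = []
    for i in range(m):
        for b in range(B):
            rng = stream(seed, "plan", i, b)
            in_sample = rng.integers(0, n, size=n)
            oob = np.setdiff1d(np.arange(n), in_sample)
            plans.append(BootstrapPlan(i, b, in_sample, oob))
    return plans


def mean_unique_fraction(plans: list[BootstrapPlan], n: int) -> float:
    """Mean fraction of distinct patients inside the bootstrap samples
    (analytically 1-(1-1/n)^n -> 1-1/e ~ 0.632)."""
    return float(np.mean([np.unique(p.in_sample).size / n for p in plans]))


# ---------------------------------------------------------------------------
# Out-of-bag prediction generation
# ---------------------------------------------------------------------------


@dataclass
class OOBStore:
    """Running out-of-sample prediction sums/counts per (patient, learner)."""

    learner_names: list[str]
    positions: np.ndarray          # original table row positions of eligible patients
    sums: np.ndarray               # n_eligible x L
    counts: np.ndarray             # n_eligible x L


@dataclass
class ModelRecord:
    """One fitted base model with its plan and out-of-bag evaluation set."""

    plan: BootstrapPlan
    learner_name: str
    learner: FittedLearner


@dataclass
class OOBResult:
    store: OOBStore
    plan_metrics: pd.DataFrame     # one row per (plan, learner)
    models: list[ModelRecord]
    logs: list | None = None       # optional raw (imp, rep, learner, oob, preds)


def generate_oob_predictions(stack: ImputationStack, plans: list[BootstrapPlan],
                             specs: tuple[LearnerSpec, ...], task: str, seed: int = 0,
                             keep_models: bool = True, keep_logs: bool = False) -> OOBResult:
    """Fit every base-learner on every plan's in-sample rows and accumulate
    predictions for the out-of-bag rows only.

    A hard assertion guarantees no in-sample patient ever contributes to the
    store.  Per-plan out-of-bag metrics are retained for the base-learner
    evaluation protocol.
    """
    table0 = stack.datasets[0]
    schema = table0.schema
    eligible = outcome_availability_mask(table0, task)
    n_elig = eligible.size
    ycol = schema.y_cont if task == "continuous" else schema.y_bin
    y_all = table0.data[ycol].to_numpy(dtype=float)[eligible]
    names = [s.name for s in specs]
    sums = np.zeros((n_elig, len(specs)))
    counts = np.zeros((n_elig, len(specs)), dtype=int)
    rows, models, logs = [], [], ([] if keep_logs else None)
    for plan in plans:
        if plan.in_sample.size != n_elig:
            raise InvalidArgument("plans must be drawn over the outcome-observed patients")
        overlap = np.intersect1d(plan.oob, plan.in_sample)
        assert overlap.size == 0, "leakage: out-of-bag set intersects the bootstrap sample"
        dfp = stack.datasets[plan.imputation].data.iloc[eligible]
        df_tr = dfp.iloc[plan.in_sample]
        y_tr = y_all[plan.in_sample]
        df_oob = dfp.iloc[plan.oob]
        y_oob = y_all[plan.oob]
        for li, spec in enumerate(specs):
            learner = spec.fit(df_tr, y_tr, task, schema,
                               stream_seed(seed, "fit", plan.imputation, plan.replicate, spec.name))
            preds = learner.predict(df_oob)
            sums[plan.oob, li] += preds
            counts[plan.oob, li] += 1
            row = {"imputation": plan.imputation, "replicate": plan.replicate, "learner": spec.name}
            if task == "continuous":
                row["MAE"] = mae(y_oob, preds).value
            else:
                try:
                    row["AUC"] = auc(y_oob, preds).value
                except UndefinedAUC:
                    row["AUC"] = np.nan
                row["calib_diff"] = calibration_in_the_large(y_oob, np.clip(preds, 0, 1))[2]
            rows.append(row)
            if keep_models:
                models.append(ModelRecord(plan, spec.name, learner))
            if keep_logs:
                logs.append((plan.imputation, plan.replicate, spec.name,
                             plan.oob.copy(), preds.copy()))
    store = OOBStore(names, eligible, sums, counts)
    return OOBResult(store, pd.DataFrame(rows), models, logs)


# ---------------------------------------------------------------------------
# Meta features
# ---------------------------------------------------------------------------


@dataclass
class MetaFeatures:
    """Per-patient averaged out-of-bag predictions (the meta design matrix).

    ``frame`` is indexed by original table row position; default columns are
    ``pred_<learner>`` for the two base-learners."""

    frame: pd.DataFrame
    never_oob: np.ndarray  # row positions excluded because count == 0

    @property
    def prediction_columns(self) -> list[str]:
        return [c for c in self.frame.columns if c.startswith("pred_")]


def average_oob(store: OOBStore) -> MetaFeatures:
    """Average sums/counts into one row per patient; patients that were
    in-sample in every replicate are excluded with a warning."""
    never = (store.counts == 0).any(axis=1)
    if never.all():
        raise EmptyMetaFeatures("every patient was in-sample in every bootstrap replicate")
    if never.any():
        warnings.warn(f"{int(never.sum())} patient(s) never out-of-bag; excluded from meta-training")
    keep = ~never
    avg = store.sums[keep] / store.counts[keep]
    frame = pd.DataFrame(avg, columns=[f"pred_{n}" for n in store.learner_names],
                         index=store.positions[keep])
    return MetaFeatures(frame=frame, never_oob=store.positions[never])


def augment_with_covariates(features: MetaFeatures, table: CohortTable,
                            covariates: list[str]) -> MetaFeatures:
    """Append patient covariates (from an imputed dataset) as extra meta
    inputs: one numeric column per covariate, categoricals as level codes."""
    frame = features.frame.copy()
    for name in covariates:
        pred = table.schema.predictor(name)  # raises InvalidArgument if unknown
        vals = table.data[name].iloc[frame.index.to_numpy()]
        if vals.isna().any():
            raise InvalidArgument(f"covariate {name!r} has missing values; impute first")
        if pred.kind == "categorical":
            codes = pd.Categorical(vals, categories=list(pred.levels)).codes.astype(float)
            col = codes
        else:
            col = vals.to_numpy(dtype=float)
        for existing in frame.columns:
            if np.allclose(frame[existing].to_numpy(dtype=float), col):
                warnings.warn(f"covariate {name!r} is collinear with column {existing!r}")
        frame[name] = col
    return MetaFeatures(frame=frame, never_oob=features.never_oob)


# ---------------------------------------------------------------------------
# Meta-learners
# ---------------------------------------------------------------------------


def _meta_matrix(features) -> np.ndarray:
    if isinstance(features, MetaFeatures):
        return features.frame.to_numpy(dtype=float)
    if isinstance(features, pd.DataFrame):
        return features.to_numpy(dtype=float)
    return np.asarray(features, dtype=float)


@dataclass
class MetaLinear:
    """Unregularized linear / logistic meta-learner.

    Fitting uses minimum-norm least squares (continuous) or IRLS maximum
    likelihood with pseudo-inverse steps (binary), so perfectly collinear
    prediction columns degrade gracefully instead of acquiring a silent
    penalty."""

    task: str
    columns: list[str]
    coef: np.ndarray
    intercept: float

    def predict(self, features) -> np.ndarray:
        X = _meta_matrix(features)
        eta = X @ self.coef + self.intercept
        return expit(eta) if self.task == "binary" else eta


def fit_meta_linear(features, y, task: str) -> MetaLinear:
    """Fit the linear (continuous) or logistic (binary) meta-learner without
    any regularization on the averaged base-learner predictions."""
    X = _meta_matrix(features)
    y = np.asarray(y, dtype=float)
    if X.shape[0] < 3:
        raise InvalidArgument("meta-learner needs >= 3 rows")
    if X.shape[0] != y.size:
        raise InvalidArgument("features and y length mismatch")
    cols = list(features.frame.columns) if isinstance(features, MetaFeatures) else \
        (list(features.columns) if isinstance(features, pd.DataFrame) else
         [f"x{i}" for i in range(X.shape[1])])
    Xi = np.column_stack([np.ones(X.shape[0]), X])
    if np.linalg.matrix_rank(Xi) < Xi.shape[1]:
        warnings.warn("collinear meta features; using minimum-norm pseudo-inverse solution")
    if task == "continuous":
        beta, *_ = np.linalg.lstsq(Xi, y, rcond=None)
    elif task == "binary":
        beta = _irls_logistic(Xi, y)
    else:
        raise InvalidArgument(f"unknown task {task!r}")
    return MetaLinear(task, cols, beta[1:], float(beta[0]))


def _irls_logistic(X: np.ndarray, y: np.ndarray, max_iter: int = 100,
                   tol: float = 1e-12) -> np.ndarray:
    """Newton/IRLS maximum-likelihood logistic fit with pinv steps."""
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        p = expit(eta)
        w = p * (1.0 - p) + 1e-12
        grad = X.T @ (y - p)
        H = X.T @ (X * w[:, None])
        step = np.linalg.pinv(H) @ grad
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    else:
        if np.max(np.abs(beta)) > 1e3:
            warnings.warn("logistic meta-learner may be separated; estimates did not stabilize")
    return beta


@dataclass
class MetaMLP:
    """MLP meta-learner on the (default two) prediction columns."""

    task: str
    columns: list[str]
    core: object

    def predict(self, features) -> np.ndarray:
        return self.core.predict(_meta_matrix(features))

    @property
    def architecture(self) -> tuple[int, ...]:
        return tuple(self.core.model.hidden_layer_sizes)


def fit_meta_mlp(features, y, task: str, seed: int = 0,
                 hyper: MLPHyper = MLPHyper()) -> MetaMLP:
    """Fit the MLP meta-learner (default 3 hidden layers x 256 units)."""
    X = _meta_matrix(features)
    y = np.asarray(y, dtype=float)
    if X.shape[0] != y.size:
        raise InvalidArgument("features and y length mismatch")
    cols = list(features.frame.columns) if isinstance(features, MetaFeatures) else \
        [f"x{i}" for i in range(X.shape[1])]
    core = fit_mlp_array(X, y, task, hyper, stream_seed(seed, "meta-mlp"))
    return MetaMLP(task, cols, core)


# ---------------------------------------------------------------------------
# End-to-end stacked model (development + prediction for new patients)
# ---------------------------------------------------------------------------


@dataclass
class StackedModel:
    """Everything developed on a training cohort for one task: frozen
    imputers, all fitted base models, the meta features and meta-learners."""

    task: str
    schema: object
    stack: ImputationStack
    oob: OOBResult
    features: MetaFeatures
    y_meta: np.ndarray
    meta_linear: MetaLinear
    meta_mlp: MetaMLP
    seed: int

    def predict_new(self, table: CohortTable, seed: int | None = None) -> dict[str, np.ndarray]:
        """Predict all four models for new patients.

        Each imputation copy's frozen imputer completes the new predictors
        (single seeded draw); every stored base model predicts; predictions
        are averaged per learner and fed to the meta-learners — mirroring
        how the meta inputs were constructed during development."""
        seed = self.seed if seed is None else seed
        names = self.oob.store.learner_names
        sums = {n: np.zeros(table.n) for n in names}
        counts = {n: 0 for n in names}
        completed = {j: self.stack.imputers[j].transform(table, stream_seed(seed, "new", j))
                     for j in range(self.stack.m)}
        for rec in self.oob.models:
            df = completed[rec.plan.imputation].data
            sums[rec.learner_name] += rec.learner.predict(df)
            counts[rec.learner_name] += 1
        base = {n: sums[n] / counts[n] for n in names}
        meta_X = np.column_stack([base[n] for n in names])
        out = dict(base)
        out["meta_linear"] = self.meta_linear.predict(meta_X)
        out["meta_mlp"] = self.meta_mlp.predict(meta_X)
        return out


def develop_stacked_models(table: CohortTable, task: str, m: int = 10, B: int = 20,
                           seed: int = 0, specs: tuple[LearnerSpec, ...] | None = None,
                           meta_hyper: MLPHyper = MLPHyper(), cycles: int = 5,
                           keep_logs: bool = False) -> StackedModel:
    """Run the full development pipeline on one cohort for one task:
    impute -> bootstrap plans -> out-of-bag base predictions -> average ->
    fit both meta-learners."""
    specs = specs if specs is not None else default_base_learners()
    stack = impute(table, m=m, seed=stream_seed(seed, "impute"), cycles=cycles)
    eligible = outcome_availability_mask(table, task)
    plans = make_bootstrap_plans(eligible.size, m, B, stream_seed(seed, "plans"))
    oob = generate_oob_predictions(stack, plans, specs, task,
                                   seed=stream_seed(seed, "oob"), keep_logs=keep_logs)
    features = average_oob(oob.store)
    ycol = table.schema.y_cont if task == "continuous" else table.schema.y_bin
    y_meta = table.data[ycol].to_numpy(dtype=float)[features.frame.index.to_numpy()]
    meta_lin = fit_meta_linear(features, y_meta, task)
    meta_mlp = fit_meta_mlp(features, y_meta, task, seed=stream_seed(seed, "meta"),
                            hyper=meta_hyper)
    return StackedModel(task, table.schema, stack, oob, features, y_meta,
                        meta_lin, meta_mlp, seed)
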