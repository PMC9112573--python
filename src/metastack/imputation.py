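"""Multiple imputation by chained additive spline regressions.

Each incomplete variable is regressed on every other predictor plus both
outcome columns; continuous variables enter the imputation designs through
4-knot restricted cubic splines, matching the downstream analysis model.
Continuous targets are completed by predictive-mean matching (draw an
observed value from the 5 nearest predicted-mean donors); categorical and
binary targets by a draw from multinomial-logistic class probabilities.
Each cycle refits on a bootstrap resample of the observed rows so the
imputations are proper (parameter uncertainty propagates into the draws).

Policy on outcomes: outcome columns are part of the chained system — they
inform predictor imputation and are themselves completed internally so
they can serve as predictors — but the returned datasets keep the
outcomes' original missingness pattern.  Imputed outcomes are never
available for model development or evaluation; downstream code restricts
to :func:`outcome_availability_mask`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from ._rng import stream, stream_seed
from .cohort import CohortTable, PredictorSchema
from .exceptions import DegeneratePredictor, InvalidArgument, UnimputableColumn
from .splines import place_knots, rcs_basis

DEFAULT_M = 10
DEFAULT_CYCLES = 5
DEFAULT_DONORS = 5


@dataclass
class ImputationStack:
    """m completed copies of a cohort sharing patient identity and order."""

    datasets: list[CohortTable]
    m: int
    seed: int
    cycles: int
    imputers: list["FrozenImputer"]

    def __post_init__(self):
        if self.m != len(self.datasets):
            raise InvalidArgument("m must equal the number of completed datasets")


def outcome_availability_mask(table: CohortTable, outcome: str) -> np.ndarray:
    """Positional indices of patients with an observed value of ``outcome``
    (``"continuous"`` or ``"binary"``); all fitting and evaluation for that
    outcome restricts to this set."""
    if outcome == "continuous":
        col = table.schema.y_cont
    elif outcome == "binary":
        col = table.schema.y_bin
    else:
        raise InvalidArgument(f"unknown outcome {outcome!r}")
    return np.flatnonzero(table.data[col].notna().to_numpy())


# ---------------------------------------------------------------------------
# Column models
# ---------------------------------------------------------------------------


def _col_kind(name: str, schema: PredictorSchema) -> str:
    if name == schema.y_cont:
        return "continuous"
    if name == schema.y_bin:
        return "binary"
    return schema.predictor(name).kind


def _design_terms(target: str, system_cols: list[str], work: pd.DataFrame,
                  schema: PredictorSchema) -> list[tuple]:
    """Frozen term list for the design used to impute ``target``."""
    terms = []
    for name in system_cols:
        if name == target:
            continue
        kind = _col_kind(name, schema)
        if kind == "continuous":
            x = work[name].to_numpy(dtype=float)
            try:
                terms.append((name, "rcs", place_knots(x, 4)))
            except DegeneratePredictor:
                terms.append((name, "linear", None))
        elif kind == "binary":
            terms.append((name, "linear", None))
        else:
            terms.append((name, "onehot", schema.predictor(name).levels[1:]))
    return terms


def _build_design(work: pd.DataFrame, terms: list[tuple]) -> np.ndarray:
    cols = [np.ones((len(work), 1))]
    for name, form, aux in terms:
        if form == "rcs":
            cols.append(rcs_basis(work[name].to_numpy(dtype=float), aux))
        elif form == "linear":
            cols.append(work[name].to_numpy(dtype=float)[:, None])
        else:
            vals = work[name].to_numpy(dtype=object)
            block = np.zeros((len(work), len(aux)))
            for j, lv in enumerate(aux):
                block[:, j] = vals == lv
            cols.append(block)
    return np.hstack(cols)


@dataclass
class _ColumnModel:
    name: str
    kind: str
    terms: list
    beta: np.ndarray | None = None          # continuous targets
    classifier: object | None = None        # categorical/binary targets
    classes: np.ndarray | None = None
    scaler: tuple[np.ndarray, np.ndarray] | None = None  # classifier design (mean, sd)
    donor_values: np.ndarray | None = None  # PMM donors (observed values)
    donor_preds: np.ndarray | None = None   # their predicted means, sorted


def _pmm_draw(pred_missing: np.ndarray, donor_preds: np.ndarray, donor_values: np.ndarray,
              donors: int, rng: np.random.Generator) -> np.ndarray:
    """For each predicted mean, draw one observed value from its ``donors``
    nearest donors by predicted mean."""
    n_obs = donor_preds.size
    pos = np.searchsorted(donor_preds, pred_missing)
    out = np.empty(pred_missing.size)
    for i, p in enumerate(pos):
        lo = max(0, p - donors)
        hi = min(n_obs, p + donors)
        window = np.arange(lo, hi)
        d = np.abs(donor_preds[window] - pred_missing[i])
        nearest = window[np.argsort(d, kind="stable")[:donors]]
        out[i] = donor_values[nearest[rng.integers(0, nearest.size)]]
    return out


def _fit_column(work: pd.DataFrame, target: str, obs: np.ndarray, system_cols: list[str],
                schema: PredictorSchema, donors: int, rng: np.random.Generator,
                seed: int) -> _ColumnModel:
    kind = _col_kind(target, schema)
    terms = _design_terms(target, system_cols, work, schema)
    boot = rng.choice(obs, size=obs.size, replace=True)
    Xb = _build_design(work.iloc[boot], terms)
    model = _ColumnModel(target, kind, terms)
    if kind == "continuous":
        yb = work[target].to_numpy(dtype=float)[boot]
        beta, *_ = np.linalg.lstsq(Xb, yb, rcond=None)
        model.beta = beta
        Xo = _build_design(work.iloc[obs], terms)
        preds = Xo @ beta
        order = np.argsort(preds, kind="stable")
        model.donor_preds = preds[order]
        model.donor_values = work[target].to_numpy(dtype=float)[obs][order]
    else:
        yb = work[target].to_numpy()[boot]
        if np.unique(pd.Series(yb).astype(str)).size < 2:
            # bootstrap collapsed to one class; refit on all observed rows
            Xb = _build_design(work.iloc[obs], terms)
            yb = work[target].to_numpy()[obs]
        mu = Xb.mean(axis=0)
        sd = Xb.std(axis=0)
        sd[sd == 0] = 1.0
        model.scaler = (mu, sd)
        clf = LogisticRegression(max_iter=500, C=1.0, random_state=seed)
        clf.fit((Xb - mu) / sd, pd.Series(yb).astype(str))
        model.classifier = clf
        model.classes = clf.classes_
    return model


def _draw_column(model: _ColumnModel, work: pd.DataFrame, miss: np.ndarray,
                 donors: int, rng: np.random.Generator):
    Xm = _build_design(work.iloc[miss], model.terms)
    if model.kind == "continuous":
        pred = Xm @ model.beta
        return _pmm_draw(pred, model.donor_preds, model.donor_values, donors, rng)
    mu, sd = model.scaler
    proba = model.classifier.predict_proba((Xm - mu) / sd)
    cum = np.cumsum(proba, axis=1)
    u = rng.random(len(miss))
    idx = (u[:, None] > cum).sum(axis=1)
    drawn = model.classes[np.minimum(idx, len(model.classes) - 1)]
    if model.kind == "binary":
        return drawn.astype(float)
    return drawn.astype(object)


# ---------------------------------------------------------------------------
# Engine
# ---------------------------------------------------------------------------


@dataclass
class FrozenImputer:
    """Final-cycle column models of one completed copy, reusable on new data
    (e.g. a held-out validation region) without refitting."""

    schema: PredictorSchema
    system_cols: list[str]
    impute_cols: list[str]
    models: dict[str, _ColumnModel]
    marginals: dict[str, np.ndarray]  # observed training values, for initialization
    donors: int = DEFAULT_DONORS

    def transform(self, table: CohortTable, seed: int, passes: int = 2) -> CohortTable:
        """Complete the predictors of ``table`` with a single seeded draw from
        the frozen training models; outcome missingness is preserved."""
        rng = stream(seed, "frozen-impute")
        out = table.copy()
        work = out.data[self.system_cols].copy()
        miss_map = {c: np.flatnonzero(work[c].isna().to_numpy()) for c in self.system_cols}
        for c, miss in miss_map.items():
            if miss.size:
                pool = self.marginals[c]
                filled = pool[rng.integers(0, pool.size, miss.size)]
                work.iloc[miss, work.columns.get_loc(c)] = filled
        for _ in range(passes):
            for c in self.impute_cols:
                miss = miss_map[c]
                if miss.size == 0 or c not in self.models:
                    continue
                vals = _draw_column(self.models[c], work, miss, self.donors, rng)
                work.iloc[miss, work.columns.get_loc(c)] = vals
        for c in self.schema.names:
            out.data[c] = work[c].to_numpy()
        return out


def impute(table: CohortTable, m: int = DEFAULT_M, seed: int = 0,
           cycles: int = DEFAULT_CYCLES, donors: int = DEFAULT_DONORS) -> ImputationStack:
    """Produce ``m`` stochastic completions of the cohort's predictors.

    Copy j runs on the named stream of ``seed + j`` so each completed
    dataset is independently reproducible.
    """
    if m < 1:
        raise InvalidArgument("m must be >= 1")
    schema = table.schema
    df = table.data
    system_cols = schema.names + [schema.y_cont, schema.y_bin]
    for c in schema.names:
        if df[c].isna().all():
            raise UnimputableColumn(f"predictor {c!r} is entirely missing")
    # outcomes entirely missing are dropped from the chained system
    system_cols = [c for c in system_cols if not df[c].isna().all()]
    if not any(df[c].notna().all() for c in system_cols):
        raise InvalidArgument("imputation needs at least one fully observed column")

    impute_cols = [c for c in system_cols if df[c].isna().any()]
    impute_cols.sort(key=lambda c: df[c].isna().mean())
    miss_map = {c: np.flatnonzero(df[c].isna().to_numpy()) for c in impute_cols}
    obs_map = {c: np.flatnonzero(df[c].notna().to_numpy()) for c in impute_cols}
    marginals = {c: df[c].dropna().to_numpy() for c in system_cols}

    datasets, imputers = [], []
    for j in range(m):
        rng = stream(seed + j, "impute")
        work = df[system_cols].copy()
        for c in impute_cols:
            miss = miss_map[c]
            pool = marginals[c]
            work.iloc[miss, work.columns.get_loc(c)] = pool[rng.integers(0, pool.size, miss.size)]
        models: dict[str, _ColumnModel] = {}
        for cycle in range(cycles):
            for c in impute_cols:
                model = _fit_column(work, c, obs_map[c], system_cols, schema, donors,
                                    rng, stream_seed(seed + j, "clf", cycle, c))
                work.iloc[miss_map[c], work.columns.get_loc(c)] = _draw_column(
                    model, work, miss_map[c], donors, rng)
                models[c] = model
        out = table.copy()
        for c in schema.names:
            out.data[c] = work[c].to_numpy() if c in system_cols else out.data[c]
        # outcomes keep their original missingness in the returned copy
        datasets.append(out)
        imputers.append(FrozenImputer(schema, system_cols, impute_cols, models,
                                      marginals, donors))
    return ImputationStack(datasets=datasets, m=m, seed=seed, cycles=cycles, imputers=imputers)
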