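"""The two base-learners: penalized spline regression and an MLP.

The statistical learner is a ridge regression whose design expands each of
the three spline-flagged continuous predictors (age, BMI, baseline
severity) into a 4-knot restricted cubic spline basis, one-hot encodes the
categorical predictors (no reference level dropped — the penalty absorbs
the collinearity) and passes binary flags through.  The intercept is never
penalized; the penalty is chosen by internal 5-fold cross-validation over
a 25-point log grid from 1e-4 to 1e4 unless fixed explicitly.

The machine-learning learner is a multi-layer perceptron with 3 hidden
layers of 256 units each (ReLU, adaptive-moment optimizer, batch size 256,
up to 100 epochs with early stopping on a 10% internal validation split),
with its inputs standardized internally.

All preprocessing state (scalers, spline knots, category lists) is frozen
on the training data and replayed verbatim at prediction time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.model_selection import KFold
from sklearn.neural_network import MLPClassifier, MLPRegressor
from sklearn.preprocessing import StandardScaler

from ._rng import stream_seed
from .cohort import PredictorSchema
from .exceptions import DegenerateFit, DegeneratePredictor, InvalidArgument, SchemaError
from .splines import place_knots, rcs_basis

PENALTY_GRID = np.logspace(-4, 4, 25)


@dataclass(frozen=True)
class PreprocessSpec:
    """Continuous-predictor preprocessing mode; parameters come from training rows only."""

    mode: str = "none"  # none | standardize | normalize

    def __post_init__(self):
        if self.mode not in ("none", "standardize", "normalize"):
            raise InvalidArgument(f"unknown preprocess mode {self.mode!r}")


class DesignBuilder:
    """Frozen predictor -> design-matrix transform.

    ``blocks`` maps each predictor name to its column slice in the design,
    which lets permutation importance shuffle a predictor's whole block
    without re-running the transform.
    """

    def __init__(self, schema: PredictorSchema, preprocess: PreprocessSpec = PreprocessSpec(),
                 knots: int = 4, drop_first: bool = False):
        self.schema = schema
        self.preprocess = preprocess
        self.knots = knots
        self.drop_first = drop_first
        self.fitted = False

    def fit(self, df: pd.DataFrame) -> "DesignBuilder":
        if len(df) == 0:
            raise InvalidArgument("cannot fit a design on an empty table")
        self.cont_params_: dict[str, tuple[float, float]] = {}
        self.spline_specs_: dict[str, object] = {}
        for p in self.schema.predictors:
            if p.kind != "continuous":
                continue
            x = df[p.name].to_numpy(dtype=float)
            if self.preprocess.mode == "standardize":
                sd = float(np.std(x))
                self.cont_params_[p.name] = (float(np.mean(x)), sd if sd > 0 else 1.0)
            elif self.preprocess.mode == "normalize":
                rng_ = float(np.ptp(x))
                self.cont_params_[p.name] = (float(np.min(x)), rng_ if rng_ > 0 else 1.0)
            else:
                self.cont_params_[p.name] = (0.0, 1.0)
            if p.spline:
                shift, scale = self.cont_params_[p.name]
                try:
                    self.spline_specs_[p.name] = place_knots((x - shift) / scale, self.knots)
                except DegeneratePredictor:
                    raise
        self.feature_names_: list[str] = []
        self.blocks_: dict[str, slice] = {}
        col = 0
        for p in self.schema.predictors:
            if p.kind == "continuous" and p.spline:
                w = self.spline_specs_[p.name].n_columns
                names = [p.name] + [f"{p.name}_rcs{j}" for j in range(1, w)]
            elif p.kind == "continuous" or p.kind == "binary":
                w, names = 1, [p.name]
            else:
                levels = list(p.levels)
                if self.drop_first:
                    levels = levels[1:]
                w, names = len(levels), [f"{p.name}={lv}" for lv in levels]
            self.blocks_[p.name] = slice(col, col + w)
            self.feature_names_ += names
            col += w
        self.n_features_ = col
        self.fitted = True
        return self

    def transform(self, df: pd.DataFrame) -> np.ndarray:
        if not self.fitted:
            raise InvalidArgument("DesignBuilder not fitted")
        missing_cols = [n for n in self.schema.names if n not in df.columns]
        if missing_cols:
            raise SchemaError(f"input lacks predictor columns {missing_cols}")
        n = len(df)
        Z = np.empty((n, self.n_features_))
        for p in self.schema.predictors:
            sl = self.blocks_[p.name]
            if p.kind == "continuous":
                x = df[p.name].to_numpy(dtype=float)
                if np.isnan(x).any():
                    raise SchemaError(f"missing values in predictor {p.name!r}; impute first")
                shift, scale = self.cont_params_[p.name]
                xt = (x - shift) / scale
                Z[:, sl] = rcs_basis(xt, self.spline_specs_[p.name]) if p.spline else xt[:, None]
            elif p.kind == "binary":
                x = df[p.name].to_numpy(dtype=float)
                if np.isnan(x).any():
                    raise SchemaError(f"missing values in predictor {p.name!r}; impute first")
                Z[:, sl] = x[:, None]
            else:
                vals = df[p.name].to_numpy(dtype=object)
                if pd.isna(vals).any():
                    raise SchemaError(f"missing values in predictor {p.name!r}; impute first")
                unknown = set(vals) - set(p.levels)
                if unknown:
                    raise SchemaError(f"unknown levels {sorted(unknown)} in predictor {p.name!r}")
                levels = list(p.levels)[1:] if self.drop_first else list(p.levels)
                block = np.zeros((n, len(levels)))
                for j, lv in enumerate(levels):
                    block[:, j] = vals == lv
                Z[:, sl] = block
        return Z


@dataclass(frozen=True)
class MLPHyper:
    """MLP training configuration (shared by base and meta MLPs)."""

    width: int = 256
    depth: int = 3
    batch_size: int = 256
    max_epochs: int = 100
    patience: int = 10
    validation_fraction: float = 0.1
    learning_rate_init: float = 1e-3
    alpha: float = 1e-4  # small L2 on the weights, conventional default

    @property
    def hidden_layer_sizes(self) -> tuple[int, ...]:
        return (self.width,) * self.depth


# ---------------------------------------------------------------------------
# Model cores (operate on design matrices)
# ---------------------------------------------------------------------------


class _RidgeCore:
    """L2-penalized linear / logistic model with unpenalized intercept."""

    def __init__(self, task: str):
        self.task = task
        self.coef: np.ndarray | None = None
        self.intercept: float | None = None
        self.logistic = None
        self.penalty_: float | None = None

    def predict(self, Z: np.ndarray) -> np.ndarray:
        if self.task == "binary":
            return self.logistic.predict_proba(Z)[:, 1]
        return Z @ self.coef + self.intercept


def _ridge_solve(Z: np.ndarray, y: np.ndarray, lam: float) -> tuple[np.ndarray, float]:
    """Centered ridge solution; intercept unpenalized by centering."""
    zbar = Z.mean(axis=0)
    ybar = y.mean()
    Zc = Z - zbar
    yc = y - ybar
    if lam == 0.0:
        coef, *_ = np.linalg.lstsq(Zc, yc, rcond=None)
    else:
        U, s, Vt = np.linalg.svd(Zc, full_matrices=False)
        coef = Vt.T @ ((s / (s**2 + lam)) * (U.T @ yc))
    return coef, float(ybar - zbar @ coef)


def _ridge_cv_continuous(Z: np.ndarray, y: np.ndarray, seed: int, folds: int = 5,
                         grid: np.ndarray = PENALTY_GRID) -> float:
    kf = KFold(n_splits=min(folds, len(y)), shuffle=True, random_state=seed % (2**31))
    sse = np.zeros(len(grid))
    for tr, va in kf.split(Z):
        zbar = Z[tr].mean(axis=0)
        ybar = y[tr].mean()
        Zc, yc = Z[tr] - zbar, y[tr] - ybar
        U, s, Vt = np.linalg.svd(Zc, full_matrices=False)
        Uty = U.T @ yc
        Zv = Z[va] - zbar
        for i, lam in enumerate(grid):
            coef = Vt.T @ ((s / (s**2 + lam)) * Uty)
            pred = Zv @ coef + ybar
            sse[i] += float(np.sum((y[va] - pred) ** 2))
    return float(grid[int(np.argmin(sse))])


def fit_ridge(df: pd.DataFrame, y, task: str, schema: PredictorSchema,
              preprocess: PreprocessSpec = PreprocessSpec(), seed: int = 0,
              penalty: float | str = "cv") -> "FittedLearner":
    """Fit the penalized spline regression base-learner.

    ``penalty`` is the L2 strength lambda, or ``"cv"`` for internal 5-fold
    selection.  For the binary task the model is a penalized logistic
    regression on the same design; predictions are probabilities.
    """
    _check_xy(df, y, task)
    y = np.asarray(y, dtype=float)
    builder = DesignBuilder(schema, preprocess).fit(df)
    Z = builder.transform(df)
    core = _RidgeCore(task)
    if task == "continuous":
        lam = _ridge_cv_continuous(Z, y, stream_seed(seed, "ridge-cv")) if penalty == "cv" else float(penalty)
        core.coef, core.intercept = _ridge_solve(Z, y, lam)
        core.penalty_ = lam
    else:
        if penalty == "cv":
            model = LogisticRegressionCV(
                Cs=list(1.0 / PENALTY_GRID), cv=min(5, max(2, len(y) // 2)),
                solver="lbfgs", max_iter=2000, scoring="neg_log_loss",
                random_state=stream_seed(seed, "ridge-cv"),
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", FutureWarning)
                model.fit(Z, y)
            core.penalty_ = float(1.0 / model.C_[0])
        elif float(penalty) == 0.0:
            model = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=5000, tol=1e-10)
            model.fit(Z, y)
            core.penalty_ = 0.0
        else:
            model = LogisticRegression(C=1.0 / float(penalty), solver="lbfgs", max_iter=2000)
            model.fit(Z, y)
            core.penalty_ = float(penalty)
        core.logistic = model
    return FittedLearner("ridge", task, builder, seed, core)


class _MLPCore:
    def __init__(self, task: str, scaler: StandardScaler, model, hyper: MLPHyper):
        self.task = task
        self.scaler = scaler
        self.model = model
        self.hyper = hyper

    def predict(self, Z: np.ndarray) -> np.ndarray:
        Zs = self.scaler.transform(Z)
        if self.task == "binary":
            return self.model.predict_proba(Zs)[:, 1]
        return self.model.predict(Zs)


def fit_mlp_array(X: np.ndarray, y: np.ndarray, task: str, hyper: MLPHyper, seed: int) -> _MLPCore:
    """Fit an MLP on a raw numeric matrix (used by base and meta learners)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    scaler = StandardScaler().fit(X)
    Xs = scaler.transform(X)
    cls = MLPClassifier if task == "binary" else MLPRegressor
    # early stopping needs enough rows for the internal validation split
    early = len(y) >= 50
    n_train = int(len(y) * (1 - hyper.validation_fraction)) if early else len(y)
    model = cls(
        hidden_layer_sizes=hyper.hidden_layer_sizes,
        activation="relu",
        solver="adam",
        alpha=hyper.alpha,
        batch_size=min(hyper.batch_size, max(1, n_train)),
        learning_rate_init=hyper.learning_rate_init,
        max_iter=hyper.max_epochs,
        early_stopping=early,
        validation_fraction=hyper.validation_fraction,
        n_iter_no_change=hyper.patience,
        random_state=seed % (2**31),
    )
    with warnings.catch_warnings():
        from sklearn.exceptions import ConvergenceWarning

        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(Xs, y)
    return _MLPCore(task, scaler, model, hyper)


def fit_mlp(df: pd.DataFrame, y, task: str, schema: PredictorSchema,
            hyper: MLPHyper = MLPHyper(), preprocess: PreprocessSpec = PreprocessSpec(),
            seed: int = 0) -> "FittedLearner":
    """Fit the MLP base-learner (default 3 hidden layers x 256 units)."""
    _check_xy(df, y, task)
    y = np.asarray(y, dtype=float)
    builder = DesignBuilder(schema, preprocess).fit(df)
    Z = builder.transform(df)
    core = fit_mlp_array(Z, y, task, hyper, stream_seed(seed, "mlp"))
    return FittedLearner("mlp", task, builder, seed, core)


def _check_xy(df: pd.DataFrame, y, task: str) -> None:
    if task not in ("continuous", "binary"):
        raise InvalidArgument(f"unknown task {task!r}")
    if len(df) == 0:
        raise InvalidArgument("empty training data")
    y = np.asarray(y, dtype=float)
    if len(y) != len(df):
        raise InvalidArgument("X and y length mismatch")
    if np.isnan(y).any():
        raise InvalidArgument("y contains missing values; restrict to outcome-observed rows")
    if np.unique(y).size < 2:
        raise DegenerateFit("outcome is constant; nothing to fit")


@dataclass
class FittedLearner:
    """A frozen fitted model: preprocessing state + parameters + seed."""

    learner_kind: str
    task: str
    builder: DesignBuilder
    seed: int
    core: object

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        """Predict from raw predictor columns (frozen transform applied)."""
        return self.core.predict(self.builder.transform(df))

    def predict_design(self, Z: np.ndarray) -> np.ndarray:
        """Predict from a pre-built design matrix (importance fast path)."""
        return self.core.predict(Z)

    @property
    def architecture(self) -> tuple[int, ...] | None:
        """Hidden layer widths for MLPs, None for linear models."""
        if isinstance(self.core, _MLPCore):
            return tuple(self.core.model.hidden_layer_sizes)
        return None


def save_learner(learner: FittedLearner, path) -> None:
    """Serialize a fitted learner (parameters + frozen preprocessing state,
    spline knots, category lists and training seed) to ``path``."""
    import pickle
    from pathlib import Path

    Path(path).write_bytes(pickle.dumps(learner))


def load_learner(path) -> FittedLearner:
    """Inverse of :func:`save_learner`; only load archives you wrote."""
    import pickle
    from pathlib import Path

    obj = pickle.loads(Path(path).read_bytes())
    if not isinstance(obj, FittedLearner):
        raise InvalidArgument(f"{path} does not contain a fitted learner")
    return obj


def preprocessing_sensitivity(df_train: pd.DataFrame, y_train, df_test: pd.DataFrame, y_test,
                              schema: PredictorSchema, seed: int = 0,
                              penalty: float | str = "cv") -> pd.DataFrame:
    """Run the ridge continuous-outcome pipeline under the three preprocessing
    modes (none / standardize / normalize) and report test MAEs side by side."""
    from .metrics import mae

    rows = []
    for mode in ("none", "standardize", "normalize"):
        learner = fit_ridge(df_train, y_train, "continuous", schema,
                            preprocess=PreprocessSpec(mode), seed=seed, penalty=penalty)
        rows.append({"preprocess": mode, "test_mae": mae(y_test, learner.predict(df_test)).value})
    return pd.DataFrame(rows)
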