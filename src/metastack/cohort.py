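"""Synthetic primary-care depression cohorts.

Emulates the structure of a restricted-access UK primary-care extract used
to predict two outcomes measured 60 days after starting an antidepressant:
a PHQ-9 depression-severity score (integer, 0-27) and all-cause treatment
dropout (binary, population prevalence 37.5%).  Thirty-one baseline
predictors are generated: three continuous (age, BMI, baseline PHQ-9
severity — the spline-expanded ones downstream), twenty binary
comorbidity/demographic flags and eight categorical variables.  Patients
belong to one of ten data-collection regions with small random-intercept
heterogeneity.

The generator also returns the ground truth of its own data-generating
model (conditional means, event probabilities, coefficients) so that
downstream estimators can be tested for parameter recovery, and it can
realize a missing-at-random missingness mechanism in which the baseline
severity score is 75% missing — the dominant missingness feature of the
real extract this stands in for.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from ._rng import stream
from .exceptions import InvalidArgument

# ---------------------------------------------------------------------------
# Schema
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Predictor:
    name: str
    kind: str  # continuous | binary | categorical
    levels: tuple[str, ...] | None = None
    spline: bool = False  # expanded with restricted cubic splines downstream

    def __post_init__(self):
        if self.kind not in ("continuous", "binary", "categorical"):
            raise InvalidArgument(f"unknown predictor kind {self.kind!r}")
        if self.kind == "categorical" and (self.levels is None or len(self.levels) < 2):
            raise InvalidArgument(f"categorical predictor {self.name} needs >= 2 levels")


@dataclass(frozen=True)
class PredictorSchema:
    """Predictor taxonomy plus the fixed outcome / region / id column names."""

    predictors: tuple[Predictor, ...]
    y_cont: str = "phq9_60d"
    y_bin: str = "dropout_60d"
    region: str = "region"
    patient_id: str = "patient_id"
    regions: tuple[str, ...] = tuple(f"region_{i:02d}" for i in range(1, 11))

    @property
    def names(self) -> list[str]:
        return [p.name for p in self.predictors]

    @property
    def continuous(self) -> list[str]:
        return [p.name for p in self.predictors if p.kind == "continuous"]

    @property
    def spline_predictors(self) -> list[str]:
        return [p.name for p in self.predictors if p.spline]

    @property
    def binary(self) -> list[str]:
        return [p.name for p in self.predictors if p.kind == "binary"]

    @property
    def categorical(self) -> list[Predictor]:
        return [p for p in self.predictors if p.kind == "categorical"]

    def predictor(self, name: str) -> Predictor:
        for p in self.predictors:
            if p.name == name:
                return p
        raise InvalidArgument(f"unknown predictor {name!r}")

    def validate_default_shape(self) -> None:
        if len(self.predictors) != 31:
            raise InvalidArgument(f"default schema must have 31 predictors, got {len(self.predictors)}")
        if len(self.continuous) != 3 or len(self.spline_predictors) != 3:
            raise InvalidArgument("default schema must have exactly 3 spline-flagged continuous predictors")


# Binary flags with their marginal prevalences.
_BINARY = [
    ("female", 0.62), ("anxiety", 0.35), ("diabetes", 0.08), ("hypertension", 0.15),
    ("asthma", 0.12), ("copd", 0.04), ("cvd", 0.07), ("ckd", 0.03),
    ("epilepsy", 0.01), ("migraine", 0.09), ("osteoarthritis", 0.10),
    ("chronic_pain", 0.18), ("insomnia", 0.22), ("substance_misuse", 0.06),
    ("self_harm_history", 0.08), ("family_history_depression", 0.25),
    ("psych_referral", 0.12), ("benzodiazepine_use", 0.07),
    ("nsaid_use", 0.20), ("statin_use", 0.12),
]

# Categorical variables with levels and marginal probabilities.
_CATEGORICAL = [
    ("ethnicity", ("white", "black", "asian", "mixed", "other"), (0.75, 0.06, 0.12, 0.04, 0.03)),
    ("smoking_status", ("never", "former", "current"), (0.50, 0.25, 0.25)),
    ("alcohol_use", ("none", "low", "moderate", "high"), (0.20, 0.40, 0.30, 0.10)),
    ("townsend_quintile", ("q1", "q2", "q3", "q4", "q5"), (0.20, 0.20, 0.20, 0.20, 0.20)),
    ("employment_status", ("employed", "unemployed", "retired", "student"), (0.60, 0.15, 0.15, 0.10)),
    ("marital_status", ("single", "married", "divorced", "widowed"), (0.35, 0.40, 0.15, 0.10)),
    ("consultation_frequency", ("low", "medium", "high"), (0.30, 0.50, 0.20)),
    ("registration_period", ("1998-2004", "2005-2010", "2011-2015", "2016+"), (0.30, 0.30, 0.25, 0.15)),
]


def default_schema(n_regions: int = 10) -> PredictorSchema:
    """The 31-predictor schema: 3 continuous (spline-flagged), 20 binary, 8 categorical."""
    preds = [
        Predictor("age", "continuous", spline=True),
        Predictor("bmi", "continuous", spline=True),
        Predictor("baseline_severity", "continuous", spline=True),
    ]
    preds += [Predictor(name, "binary") for name, _ in _BINARY]
    preds += [Predictor(name, "categorical", levels=levels) for name, levels, _ in _CATEGORICAL]
    schema = PredictorSchema(
        predictors=tuple(preds),
        regions=tuple(f"region_{i:02d}" for i in range(1, n_regions + 1)),
    )
    if n_regions == 10:
        schema.validate_default_shape()
    return schema


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass
class CohortTable:
    """Patient rows: id, region, 31 typed predictors, two outcomes.

    Missing values are NaN (continuous/binary stored as float; categorical
    stored as object).  The missingness mask is therefore ``isna()`` on the
    predictor block.
    """

    data: pd.DataFrame
    schema: PredictorSchema

    @property
    def n(self) -> int:
        return len(self.data)

    def predictors(self) -> pd.DataFrame:
        return self.data[self.schema.names]

    def mask(self) -> pd.DataFrame:
        return self.predictors().isna()

    def copy(self) -> "CohortTable":
        return CohortTable(self.data.copy(), self.schema)

    def validate(self) -> None:
        s = self.schema
        df = self.data
        if df[s.patient_id].duplicated().any():
            raise InvalidArgument("duplicate patient_id values")
        if df[s.region].isna().any():
            raise InvalidArgument("region must be non-missing for all rows")
        yc = df[s.y_cont]
        obs = yc.dropna()
        if len(obs) and ((obs < 0) | (obs > 27)).any():
            raise InvalidArgument("observed continuous outcome must lie in [0, 27]")


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the data-generating model; defaults are the study conditions."""

    n: int = 10_000
    seed: int = 0
    target_prevalence: float = 0.375
    noise_sd: float = 5.0
    nonlinearity_weight: float = 1.0
    interaction_weight: float = 1.0
    region_effect_sd: float = 0.3
    cont_subset_fraction: float = 16_384 / 187_757  # fraction with observed PHQ-9 at 60d
    missing_rates: dict = field(default_factory=lambda: dict(DEFAULT_MISSING_RATES))
    n_regions: int = 10

    def validate(self) -> None:
        if self.n < 0:
            raise InvalidArgument("n must be >= 0")
        if not (0.0 < self.target_prevalence < 1.0):
            raise InvalidArgument("target_prevalence must lie in (0, 1)")
        if self.noise_sd < 0 or self.region_effect_sd < 0:
            raise InvalidArgument("scale parameters must be >= 0")
        if not (0.0 <= self.cont_subset_fraction <= 1.0):
            raise InvalidArgument("cont_subset_fraction must lie in [0, 1]")
        for name, rate in self.missing_rates.items():
            if not (0.0 <= rate <= 1.0):
                raise InvalidArgument(f"missing rate for {name} must lie in [0, 1]")


#: Default per-predictor missingness: baseline severity dominates at 75%.
DEFAULT_MISSING_RATES = {"baseline_severity": 0.75, "bmi": 0.10, "alcohol_use": 0.05}


@dataclass
class OracleTruth:
    """Ground truth of the generating model, for recovery tests."""

    mu_cont_raw: np.ndarray  # conditional mean of the latent continuous outcome
    mu_cont: np.ndarray      # same, clipped to [0, 27]
    p_bin: np.ndarray        # true event probability
    coefficients: dict
    region_effects: dict


# ---------------------------------------------------------------------------
# Generating model coefficients
# ---------------------------------------------------------------------------

# Continuous outcome: baseline severity is the dominant driver.
_CONT_BIN_COEF = {
    "anxiety": 0.8, "chronic_pain": 0.6, "insomnia": 0.5, "self_harm_history": 0.7,
    "family_history_depression": 0.3, "substance_misuse": 0.4,
}
_CONT_ETHNICITY = {"white": 0.0, "black": 0.2, "asian": -0.1, "mixed": 0.3, "other": 0.1}

# Binary outcome: ethnicity and deprivation carry most of the (weak) signal.
_BIN_ETHNICITY = {"white": 0.0, "black": 0.5, "asian": 0.3, "mixed": 0.7, "other": 0.4}
_BIN_BIN_COEF = {"substance_misuse": 0.3, "female": -0.1}

_COEF_RECORD = {
    "cont": {
        "intercept": 6.5,
        "baseline_severity": 0.50,
        "age_per_decade": -0.15,
        "bmi_per_5": 0.10,
        "binary": _CONT_BIN_COEF,
        "ethnicity": _CONT_ETHNICITY,
        "townsend_per_quintile": 0.15,
        "nonlinearity_scale": 2.5,
        "interaction_scale": 0.06,
    },
    "bin": {
        "baseline_severity": 0.02,
        "age_per_decade": -0.12,
        "binary": _BIN_BIN_COEF,
        "ethnicity": _BIN_ETHNICITY,
        "townsend_per_quintile": 0.12,
    },
}


def _nonlinear_bend(sev: np.ndarray) -> np.ndarray:
    """Smooth cubic bend in baseline severity, zero below 10 — the shape a
    4-knot restricted spline can capture but a linear term cannot."""
    return 2.5 * (np.clip(sev - 10.0, 0, None) / 17.0) ** 3


def _linear_predictor_cont(df: pd.DataFrame, cfg: GeneratorConfig) -> tuple[np.ndarray, np.ndarray]:
    """Return (pure linear part, nonlinear+interaction part) of the continuous mean."""
    c = _COEF_RECORD["cont"]
    sev_c = df["baseline_severity"].to_numpy() - 15.0
    age_c = (df["age"].to_numpy() - 50.0) / 10.0
    bmi_c = (df["bmi"].to_numpy() - 27.0) / 5.0
    lp = c["intercept"] + c["baseline_severity"] * sev_c + c["age_per_decade"] * age_c + c["bmi_per_5"] * bmi_c
    for name, b in c["binary"].items():
        lp = lp + b * df[name].to_numpy()
    lp = lp + np.vectorize(c["ethnicity"].get)(df["ethnicity"].to_numpy()).astype(float)
    q = df["townsend_quintile"].str.slice(1).astype(int).to_numpy()
    lp = lp + c["townsend_per_quintile"] * (q - 3)
    nl = (
        cfg.nonlinearity_weight * _nonlinear_bend(df["baseline_severity"].to_numpy())
        + cfg.interaction_weight * c["interaction_scale"] * sev_c * age_c
    )
    return lp, nl


def _linear_predictor_bin(df: pd.DataFrame) -> np.ndarray:
    c = _COEF_RECORD["bin"]
    sev_c = df["baseline_severity"].to_numpy() - 15.0
    age_c = (df["age"].to_numpy() - 50.0) / 10.0
    lp = c["baseline_severity"] * sev_c + c["age_per_decade"] * age_c
    for name, b in c["binary"].items():
        lp = lp + b * df[name].to_numpy()
    lp = lp + np.vectorize(c["ethnicity"].get)(df["ethnicity"].to_numpy()).astype(float)
    q = df["townsend_quintile"].str.slice(1).astype(int).to_numpy()
    lp = lp + c["townsend_per_quintile"] * (q - 3)
    return lp


def _calibrate_intercept(lp: np.ndarray, target: float) -> float:
    """Intercept a0 with mean(expit(a0 + lp)) == target on the realized sample."""
    if lp.size == 0:
        return float(logit(target))

    def f(a):
        return float(np.mean(expit(a + lp)) - target)

    lo, hi = -20.0, 20.0
    return float(brentq(f, lo, hi, xtol=1e-12))


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def generate_cohort(config: GeneratorConfig) -> tuple[CohortTable, OracleTruth]:
    """Draw a complete cohort (no missingness) plus its generating truth.

    Deterministic given ``config.seed``.  The binary-outcome intercept is
    calibrated on the realized covariates so the population event
    probability equals ``target_prevalence`` exactly in expectation.
    """
    config.validate()
    schema = default_schema(config.n_regions)
    n = config.n
    rng_x = stream(config.seed, "predictors")
    rng_r = stream(config.seed, "regions")
    rng_yc = stream(config.seed, "outcome_cont")
    rng_yb = stream(config.seed, "outcome_bin")
    rng_u = stream(config.seed, "region_effects")

    df = pd.DataFrame({schema.patient_id: np.arange(n, dtype=int)})
    df["age"] = rng_x.uniform(18.0, 90.0, n)
    df["bmi"] = np.clip(rng_x.normal(27.5, 5.0, n), 15.0, 45.0)
    df["baseline_severity"] = np.clip(rng_x.normal(16.0, 5.0, n), 0.0, 27.0)
    for name, p in _BINARY:
        df[name] = (rng_x.random(n) < p).astype(float)
    for name, levels, probs in _CATEGORICAL:
        df[name] = rng_x.choice(levels, size=n, p=probs).astype(object)
    df[schema.region] = rng_r.choice(schema.regions, size=n).astype(object)

    u = {r: float(rng_u.normal(0.0, config.region_effect_sd)) for r in schema.regions}
    region_u = df[schema.region].map(u).to_numpy(dtype=float) if n else np.zeros(0)

    if n:
        lp_lin, lp_nl = _linear_predictor_cont(df, config)
        mu_raw = lp_lin + lp_nl + region_u
        y_cont = np.clip(np.round(mu_raw + rng_yc.normal(0.0, config.noise_sd, n)), 0.0, 27.0)

        lp_b = _linear_predictor_bin(df) + region_u
        a0 = _calibrate_intercept(lp_b, config.target_prevalence)
        p_bin = expit(a0 + lp_b)
        y_bin = (rng_yb.random(n) < p_bin).astype(float)
    else:
        mu_raw = np.zeros(0)
        y_cont = np.zeros(0)
        p_bin = np.zeros(0)
        y_bin = np.zeros(0)
        a0 = float(logit(config.target_prevalence))

    df[schema.y_cont] = y_cont
    df[schema.y_bin] = y_bin

    coef = {k: dict(v) for k, v in _COEF_RECORD.items()}
    coef["bin"]["intercept"] = a0
    truth = OracleTruth(
        mu_cont_raw=mu_raw,
        mu_cont=np.clip(mu_raw, 0.0, 27.0),
        p_bin=p_bin,
        coefficients=coef,
        region_effects=u,
    )
    table = CohortTable(df, schema)
    table.validate()
    return table, truth


# MAR missingness models: probability depends only on fully observed columns.
_MAR_MODELS = {
    "baseline_severity": lambda df: (
        -0.5 * (df["age"].to_numpy() - 50.0) / 10.0
        + 0.6 * df["psych_referral"].to_numpy(dtype=float)
        + 0.3 * df["anxiety"].to_numpy(dtype=float)
    ),
    "bmi": lambda df: 0.3 * df["female"].to_numpy(dtype=float),
}


def apply_missingness(table: CohortTable, config: GeneratorConfig) -> CohortTable:
    """Mask predictor values under a missing-at-random mechanism.

    Missingness probabilities depend only on fully observed columns (age,
    referral/anxiety flags, sex), so the masked value is independent of its
    own missingness indicator given the observed data.  The continuous
    outcome is additionally masked completely at random so that a
    ``cont_subset_fraction`` share of patients keeps an observed score.
    """
    config.validate()
    if table.mask().any().any():
        raise InvalidArgument("apply_missingness expects a cohort without prior predictor missingness")
    out = table.copy()
    df = out.data
    n = len(df)
    rng = stream(config.seed, "missingness")
    for name, rate in config.missing_rates.items():
        if name not in table.schema.names:
            raise InvalidArgument(f"missing rate given for unknown predictor {name!r}")
        if rate == 0.0 or n == 0:
            continue
        if name in _MAR_MODELS:
            lp = _MAR_MODELS[name](df)
            c0 = _calibrate_intercept(lp, rate)
            p_miss = expit(c0 + lp)
        else:
            p_miss = np.full(n, rate)
        hit = rng.random(n) < p_miss
        if table.schema.predictor(name).kind == "categorical":
            df.loc[hit, name] = np.nan
        else:
            df.loc[hit, name] = np.nan

    rng_y = stream(config.seed, "outcome_subset")
    if config.cont_subset_fraction < 1.0 and n:
        keep = rng_y.random(n) < config.cont_subset_fraction
        df.loc[~keep, table.schema.y_cont] = np.nan
    return out


def simulate_cohort(config: GeneratorConfig) -> tuple[CohortTable, OracleTruth, CohortTable]:
    """Generate, then mask: returns (masked table, truth, complete table)."""
    complete, truth = generate_cohort(config)
    masked = apply_missingness(complete, config)
    return masked, truth, complete
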