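"""Base-learners: ridge-with-splines and MLP contracts."""

import dataclasses

import numpy as np
import pytest

from metastack import (GeneratorConfig, MLPHyper, Predictor, PredictorSchema,
                       PreprocessSpec, fit_mlp, fit_ridge, generate_cohort, mae,
                       preprocessing_sensitivity)
from metastack.exceptions import DegenerateFit, InvalidArgument, SchemaError
from tests.conftest import SMALL_MLP, TINY_MLP


def _xy(table, task="continuous"):
    col = table.schema.y_cont if task == "continuous" else table.schema.y_bin
    return table.data, table.data[col].to_numpy(dtype=float)


@pytest.fixture(scope="module")
def cohort300():
    table, _ = generate_cohort(GeneratorConfig(n=300, seed=50))
    return table


@pytest.fixture(scope="module")
def cohort1500():
    table, truth = generate_cohort(GeneratorConfig(n=1500, seed=51))
    return table, truth


class TestRidge:
    def test_zero_penalty_equals_ols(self, cohort300):
        df, y = _xy(cohort300)
        learner = fit_ridge(df, y, "continuous", cohort300.schema, penalty=0.0)
        Z = learner.builder.transform(df)
        Xi = np.column_stack([np.ones(len(df)), Z])
        beta, *_ = np.linalg.lstsq(Xi, y, rcond=None)
        assert np.allclose(learner.predict(df), Xi @ beta, atol=1e-6)

    def test_infinite_penalty_predicts_training_mean(self, cohort300):
        df, y = _xy(cohort300)
        learner = fit_ridge(df, y, "continuous", cohort300.schema, penalty=1e12)
        assert np.allclose(learner.predict(df), y.mean(), atol=1e-3)

    def test_infinite_penalty_binary_predicts_event_rate(self, cohort300):
        df, y = _xy(cohort300, "binary")
        learner = fit_ridge(df, y, "binary", cohort300.schema, penalty=1e7)
        assert np.allclose(learner.predict(df), y.mean(), atol=0.01)

    def test_training_loss_nondecreasing_in_penalty(self, cohort300):
        df, y = _xy(cohort300)
        losses = []
        for lam in [0.0, 1.0, 100.0, 1e4, 1e6]:
            learner = fit_ridge(df, y, "continuous", cohort300.schema, penalty=lam)
            losses.append(np.mean((y - learner.predict(df)) ** 2))
        assert all(a <= b + 1e-10 for a, b in zip(losses, losses[1:]))

    def test_prediction_is_design_times_coefficients(self, cohort300):
        df, y = _xy(cohort300)
        learner = fit_ridge(df, y, "continuous", cohort300.schema, penalty=5.0)
        five = df.head(5)
        Z5 = learner.builder.transform(five)
        by_hand = Z5 @ learner.core.coef + learner.core.intercept
        assert np.allclose(learner.predict(five), by_hand, atol=1e-12)

    def test_spline_design_beats_linear_on_bent_signal(self):
        """With a strong cubic bend in baseline severity the spline ridge
        must out-predict a ridge restricted to linear continuous terms."""
        cfg = GeneratorConfig(n=4000, seed=52, noise_sd=2.0, nonlinearity_weight=6.0,
                              interaction_weight=0.0)
        table, _ = generate_cohort(cfg)
        df, y = _xy(table)
        tr, te = np.arange(0, 3000), np.arange(3000, 4000)
        spline = fit_ridge(df.iloc[tr], y[tr], "continuous", table.schema, penalty="cv")
        linear_schema = PredictorSchema(
            predictors=tuple(dataclasses.replace(p, spline=False) for p in table.schema.predictors),
            regions=table.schema.regions)
        linear = fit_ridge(df.iloc[tr], y[tr], "continuous", linear_schema, penalty="cv")
        mae_spline = mae(y[te], spline.predict(df.iloc[te])).value
        mae_linear = mae(y[te], linear.predict(df.iloc[te])).value
        assert mae_spline < mae_linear

    def test_constant_outcome_rejected(self, cohort300):
        df, _ = _xy(cohort300)
        with pytest.raises(DegenerateFit):
            fit_ridge(df, np.ones(len(df)), "continuous", cohort300.schema)

    def test_empty_data_rejected(self, cohort300):
        df, _ = _xy(cohort300)
        with pytest.raises(InvalidArgument):
            fit_ridge(df.iloc[:0], np.array([]), "continuous", cohort300.schema)


class TestMLP:
    def test_default_architecture_is_three_by_256(self, cohort300):
        df, y = _xy(cohort300)
        learner = fit_mlp(df.head(120), y[:120], "continuous", cohort300.schema)
        assert learner.architecture == (256, 256, 256)

    def test_same_seed_identical_predictions(self, cohort300):
        df, y = _xy(cohort300)
        p1 = fit_mlp(df, y, "continuous", cohort300.schema, hyper=TINY_MLP, seed=9).predict(df)
        p2 = fit_mlp(df, y, "continuous", cohort300.schema, hyper=TINY_MLP, seed=9).predict(df)
        assert np.array_equal(p1, p2)

    def test_binary_predictions_are_probabilities(self, cohort300):
        df, y = _xy(cohort300, "binary")
        p = fit_mlp(df, y, "binary", cohort300.schema, hyper=TINY_MLP).predict(df)
        assert p.min() >= 0.0 and p.max() <= 1.0

    def test_mlp_learns_xor_where_linear_models_cannot(self, rng):
        """Pure two-flag interaction outcome: the truth table is y = a XOR b,
        which no additive logistic model can represent."""
        import pandas as pd

        n = 5000
        a = rng.integers(0, 2, n).astype(float)
        b = rng.integers(0, 2, n).astype(float)
        y = np.logical_xor(a, b).astype(float)
        flip = rng.random(n) < 0.05
        y[flip] = 1 - y[flip]
        schema = PredictorSchema(predictors=(Predictor("a", "binary"), Predictor("b", "binary")))
        df = pd.DataFrame({"a": a, "b": b})
        tr, te = np.arange(4000), np.arange(4000, n)
        mlp = fit_mlp(df.iloc[tr], y[tr], "binary", schema, hyper=SMALL_MLP, seed=1)
        ridge = fit_ridge(df.iloc[tr], y[tr], "binary", schema, penalty=0.0)
        acc_mlp = np.mean((mlp.predict(df.iloc[te]) > 0.5) == y[te])
        acc_ridge = np.mean((ridge.predict(df.iloc[te]) > 0.5) == y[te])
        assert acc_mlp > 0.85
        assert acc_mlp > acc_ridge + 0.2


class TestFrozenPreprocessing:
    def test_no_leakage_from_test_rows(self, cohort1500):
        """Knots/scalers estimated on training rows are invariant to the
        content of any test data: predictions on a fixed probe are
        bit-identical whatever else is predicted."""
        table, _ = cohort1500
        df, y = _xy(table)
        tr = df.iloc[:1000]
        learner = fit_ridge(tr, y[:1000], "continuous", table.schema, penalty=1.0,
                            preprocess=PreprocessSpec("standardize"))
        probe = df.iloc[1000:1100]
        before = learner.predict(probe)
        _ = learner.predict(df.iloc[1100:1500])  # unrelated test data
        after = learner.predict(probe)
        assert np.array_equal(before, after)
        knots = learner.builder.spline_specs_["baseline_severity"].knots
        relearn = fit_ridge(tr, y[:1000], "continuous", table.schema, penalty=1.0,
                            preprocess=PreprocessSpec("standardize"))
        assert relearn.builder.spline_specs_["baseline_severity"].knots == knots

    def test_schema_mismatch_raises(self, cohort300):
        df, y = _xy(cohort300)
        learner = fit_ridge(df, y, "continuous", cohort300.schema, penalty=1.0)
        with pytest.raises(SchemaError):
            learner.predict(df.drop(columns=["bmi"]))

    def test_missing_values_rejected_at_predict(self, cohort300):
        df, y = _xy(cohort300)
        learner = fit_ridge(df, y, "continuous", cohort300.schema, penalty=1.0)
        broken = df.head(10).copy()
        broken.loc[broken.index[0], "age"] = np.nan
        with pytest.raises(SchemaError):
            learner.predict(broken)


class TestSerialization:
    def test_round_trip_preserves_predictions_and_knots(self, cohort300, tmp_path):
        from metastack import load_learner, save_learner

        df, y = _xy(cohort300)
        learner = fit_ridge(df, y, "continuous", cohort300.schema, penalty=2.0)
        path = tmp_path / "ridge.pkl"
        save_learner(learner, path)
        back = load_learner(path)
        assert np.array_equal(back.predict(df), learner.predict(df))
        assert back.builder.spline_specs_["age"].knots == \
            learner.builder.spline_specs_["age"].knots


class TestPreprocessingSensitivity:
    def test_three_modes_reported_and_similar(self, cohort1500):
        """The sensitivity harness runs none/standardize/normalize through
        the ridge continuous pipeline; results should be close (the spline
        + penalty pipeline is nearly invariant to affine rescaling)."""
        table, _ = cohort1500
        df, y = _xy(table)
        report = preprocessing_sensitivity(df.iloc[:1000], y[:1000], df.iloc[1000:], y[1000:],
                                           table.schema, seed=3)
        assert list(report["preprocess"]) == ["none", "standardize", "normalize"]
        maes = report["test_mae"].to_numpy()
        assert np.all(np.isfinite(maes))
        assert maes.max() / maes.min() < 1.25
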