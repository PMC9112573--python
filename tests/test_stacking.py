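"""Stacking engine: plans, out-of-bag integrity, averaging, meta-learners."""

import warnings

import numpy as np
import pandas as pd
import pytest

from metastack import (GeneratorConfig, MetaFeatures, OOBStore, augment_with_covariates,
                       average_oob, develop_stacked_models, default_base_learners,
                       fit_meta_linear, fit_meta_mlp, generate_cohort,
                       generate_oob_predictions, impute, make_bootstrap_plans,
                       mean_unique_fraction, outcome_availability_mask)
from metastack.exceptions import EmptyMetaFeatures, InvalidArgument
from metastack.learners import MLPHyper
from tests.conftest import SMALL_MLP, TINY_MLP


class TestBootstrapPlans:
    def test_default_protocol_yields_200_plans(self):
        plans = make_bootstrap_plans(50, m=10, B=20, seed=1)
        assert len(plans) == 200
        assert {(p.imputation, p.replicate) for p in plans} == {
            (i, b) for i in range(10) for b in range(20)}

    def test_plan_invariants(self):
        for p in make_bootstrap_plans(40, m=2, B=3, seed=4):
            assert p.in_sample.size == 40
            support = np.unique(p.in_sample)
            assert np.intersect1d(p.oob, support).size == 0
            assert np.array_equal(np.union1d(p.oob, support), np.arange(40))

    def test_single_patient(self):
        (plan,) = make_bootstrap_plans(1, m=1, B=1, seed=0)
        assert np.array_equal(plan.in_sample, [0]) and plan.oob.size == 0

    def test_empty_rejected(self):
        with pytest.raises(InvalidArgument):
            make_bootstrap_plans(0, 1, 1)

    def test_deterministic(self):
        p1 = make_bootstrap_plans(30, 2, 2, seed=9)
        p2 = make_bootstrap_plans(30, 2, 2, seed=9)
        for a, b in zip(p1, p2):
            assert np.array_equal(a.in_sample, b.in_sample)

    def test_unique_in_sample_fraction_near_632(self):
        plans = make_bootstrap_plans(1000, m=10, B=20, seed=2)
        assert abs(mean_unique_fraction(plans, 1000) - (1 - (1 - 1 / 1000) ** 1000)) <= 0.01


@pytest.fixture(scope="module")
def oob_small(complete_cohort):
    masked, _, _ = complete_cohort
    stack = impute(masked, m=2, seed=1, cycles=1)
    elig = outcome_availability_mask(masked, "continuous")
    plans = make_bootstrap_plans(elig.size, m=2, B=3, seed=5)
    specs = default_base_learners(mlp_hyper=TINY_MLP)
    result = generate_oob_predictions(stack, plans, specs, "continuous", seed=3,
                                      keep_logs=True)
    return masked, stack, plans, result


class TestOOBGeneration:
    def test_counts_match_plan_membership(self, oob_small):
        """Contribution count for patient i = number of plans whose oob set
        contains i, per learner — recounted from the stored plans."""
        _, _, plans, result = oob_small
        expected = np.zeros(result.store.counts.shape[0], dtype=int)
        for p in plans:
            expected[p.oob] += 1
        for li in range(result.store.counts.shape[1]):
            assert np.array_equal(result.store.counts[:, li], expected)

    def test_no_in_sample_contributions(self, oob_small):
        """Leakage audit: replaying the logs, no contribution comes from a
        patient inside its plan's bootstrap multiset."""
        _, _, plans, result = oob_small
        by_key = {(p.imputation, p.replicate): p for p in plans}
        for imp, rep, _, oob_idx, _ in result.logs:
            plan = by_key[(imp, rep)]
            assert np.intersect1d(oob_idx, plan.in_sample).size == 0

    def test_sums_match_log_replay(self, oob_small):
        _, _, _, result = oob_small
        names = result.store.learner_names
        sums = np.zeros_like(result.store.sums)
        for _, _, lname, oob_idx, preds in result.logs:
            sums[oob_idx, names.index(lname)] += preds
        assert np.allclose(sums, result.store.sums, atol=1e-12)

    def test_plan_metrics_one_row_per_plan_and_learner(self, oob_small):
        _, _, plans, result = oob_small
        assert len(result.plan_metrics) == len(plans) * 2


class TestAveraging:
    def _store(self, sums, counts):
        sums = np.asarray(sums, dtype=float)
        counts = np.asarray(counts, dtype=int)
        return OOBStore(["ridge", "mlp"], np.arange(sums.shape[0]), sums, counts)

    def test_arithmetic_mean(self):
        store = self._store([[0.6, 1.0], [0.2, 0.5]], [[2, 2], [1, 1]])
        feats = average_oob(store)
        assert np.allclose(feats.frame.to_numpy(), [[0.3, 0.5], [0.2, 0.5]])

    def test_never_oob_excluded_with_warning(self):
        store = self._store([[0.5, 0.5], [0.0, 0.0]], [[1, 1], [0, 0]])
        with pytest.warns(UserWarning, match="never out-of-bag"):
            feats = average_oob(store)
        assert len(feats.frame) == 1 and np.array_equal(feats.never_oob, [1])

    def test_all_never_oob_raises(self):
        store = self._store([[0.0, 0.0]], [[0, 0]])
        with pytest.raises(EmptyMetaFeatures):
            average_oob(store)

    def test_one_row_per_outcome_observed_patient(self, complete_cohort):
        masked, _, _ = complete_cohort
        model = develop_stacked_models(masked, "continuous", m=1, B=5, seed=2,
                                       specs=default_base_learners(mlp_hyper=TINY_MLP),
                                       meta_hyper=TINY_MLP, cycles=1)
        n_obs = outcome_availability_mask(masked, "continuous").size
        assert len(model.features.frame) + model.features.never_oob.size == n_obs


def _features(a, b):
    return MetaFeatures(pd.DataFrame({"pred_ridge": a, "pred_mlp": b}), np.array([], dtype=int))


class TestMetaLinear:
    def test_recovers_exact_base_learner(self, rng):
        y = rng.normal(size=400)
        feats = _features(y, rng.normal(size=400))
        meta = fit_meta_linear(feats, y, "continuous")
        assert np.allclose(meta.predict(feats), y, atol=1e-8)
        assert meta.coef[0] == pytest.approx(1.0, abs=1e-6)
        assert meta.coef[1] == pytest.approx(0.0, abs=1e-6)

    def test_collinear_columns_collapse_to_univariate(self, rng):
        x = rng.normal(size=300)
        y = 2 * x + rng.normal(size=300) * 0.1
        feats = _features(x, x.copy())
        with pytest.warns(UserWarning, match="collinear"):
            meta = fit_meta_linear(feats, y, "continuous")
        slope, intercept = np.polyfit(x, y, 1)
        assert np.allclose(meta.predict(feats), slope * x + intercept, atol=1e-6)

    def test_logistic_mean_prediction_equals_event_rate(self, rng):
        """Intercept score equation of the logistic MLE."""
        a = rng.random(600)
        b = rng.random(600)
        y = (rng.random(600) < 0.3 + 0.4 * a).astype(float)
        feats = _features(a, b)
        meta = fit_meta_linear(feats, y, "binary")
        assert abs(meta.predict(feats).mean() - y.mean()) < 1e-6

    def test_matches_sklearn_unpenalized_logistic(self, rng):
        from sklearn.linear_model import LogisticRegression

        a, b = rng.random((2, 500))
        y = (rng.random(500) < 0.2 + 0.5 * a).astype(float)
        feats = _features(a, b)
        meta = fit_meta_linear(feats, y, "binary")
        sk = LogisticRegression(C=np.inf, max_iter=5000, tol=1e-10).fit(
            np.column_stack([a, b]), y)
        assert np.allclose(meta.coef, sk.coef_[0], atol=1e-4)

    def test_too_few_rows_rejected(self):
        with pytest.raises(InvalidArgument):
            fit_meta_linear(_features([1.0, 2.0], [0.5, 0.2]), [1.0, 2.0], "continuous")


class TestMetaMLP:
    def test_architecture_default(self, rng):
        feats = _features(rng.random(120), rng.random(120))
        meta = fit_meta_mlp(feats, rng.normal(size=120), "continuous", seed=1)
        assert meta.architecture == (256, 256, 256)

    def test_same_seed_identical(self, rng):
        feats = _features(rng.random(200), rng.random(200))
        y = rng.normal(size=200)
        p1 = fit_meta_mlp(feats, y, "continuous", seed=4, hyper=TINY_MLP).predict(feats)
        p2 = fit_meta_mlp(feats, y, "continuous", seed=4, hyper=TINY_MLP).predict(feats)
        assert np.array_equal(p1, p2)

    def test_learns_nonlinear_combiner_better_than_linear(self, rng):
        """y = max(pred_A, pred_B): the optimal combiner is nonlinear, so the
        MLP meta-learner must beat the linear one in-sample."""
        a = rng.random(5000)
        b = rng.random(5000)
        y = np.maximum(a, b)
        feats = _features(a, b)
        lin = fit_meta_linear(feats, y, "continuous")
        mlp = fit_meta_mlp(feats, y, "continuous", seed=2, hyper=SMALL_MLP)
        mae_lin = np.mean(np.abs(y - lin.predict(feats)))
        mae_mlp = np.mean(np.abs(y - mlp.predict(feats)))
        assert mae_mlp < mae_lin


class TestAugmentation:
    @pytest.fixture(scope="class")
    def model_and_table(self, complete_cohort):
        masked, _, _ = complete_cohort
        model = develop_stacked_models(masked, "continuous", m=1, B=3, seed=6,
                                       specs=default_base_learners(mlp_hyper=TINY_MLP),
                                       meta_hyper=TINY_MLP, cycles=1)
        return model, model.stack.datasets[0]

    def test_empty_list_unchanged(self, model_and_table):
        model, table = model_and_table
        out = augment_with_covariates(model.features, table, [])
        pd.testing.assert_frame_equal(out.frame, model.features.frame)

    def test_all_31_covariates_give_33_columns(self, model_and_table):
        model, table = model_and_table
        out = augment_with_covariates(model.features, table, list(table.schema.names))
        assert out.frame.shape[1] == 33
        assert out.prediction_columns == ["pred_ridge", "pred_mlp"]

    def test_unknown_covariate_rejected(self, model_and_table):
        model, table = model_and_table
        with pytest.raises(InvalidArgument):
            augment_with_covariates(model.features, table, ["not_a_predictor"])

    def test_duplicate_column_warns(self, model_and_table):
        model, table = model_and_table
        once = augment_with_covariates(model.features, table, ["age"])
        aliased = table.copy()
        aliased.data["bmi"] = table.data["age"]
        with pytest.warns(UserWarning, match="collinear"):
            augment_with_covariates(once, aliased, ["bmi"])
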