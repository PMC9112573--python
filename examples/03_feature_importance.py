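"""Permutation feature importance for predictors and for base-learners.

Shuffles each predictor in the out-of-bag data of trained bootstrap models
and reports the percent increase in MAE (larger = more important), then
does the same for the two meta-learner input columns to quantify how much
each base-learner contributes to the stacked prediction.
"""

from metastack import (GeneratorConfig, MLPHyper, base_learner_importance,
                       default_base_learners, develop_stacked_models, meta_importance,
                       simulate_cohort)

masked, _, _ = simulate_cohort(GeneratorConfig(n=3000, seed=5, cont_subset_fraction=1.0))
hyper = MLPHyper(width=16)
model = develop_stacked_models(masked, "continuous", m=2, B=5, seed=9,
                               specs=default_base_learners(mlp_hyper=hyper),
                               meta_hyper=hyper)

imp = base_learner_importance(model.oob, model.stack, "continuous",
                              features=["baseline_severity", "age", "bmi",
                                        "anxiety", "townsend_quintile", "statin_use"],
                              n_models=5, n_shuffles=30, seed=1)
print("predictor importance (percent MAE increase under shuffling):")
print(imp.pivot(index="feature", columns="model", values="pct_change").round(2))
print("baseline severity should dominate; statin_use is a null predictor\n")

mi = meta_importance({"meta_linear": model.meta_linear, "meta_mlp": model.meta_mlp},
                     model.features, model.y_meta, "MAE", n_shuffles=50, seed=2)
print("base-learner importance for the meta-learners:")
print(mi[["model", "feature", "pct_change", "importance_ratio"]].round(2).to_string(index=False))
print("a large ratio means the meta-learner leans mostly on one base-learner")
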