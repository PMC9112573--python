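"""Develop the stacked meta-learners on one cohort and predict new patients.

Pipeline: multiple imputation -> bootstrap out-of-bag base predictions
(ridge-with-splines + MLP) -> per-patient averaging -> linear and MLP
meta-learners.  Run at desk scale (m=2 imputations, B=5 bootstraps,
width-32 MLPs) so it finishes in about a minute.
"""

import numpy as np

from metastack import (CohortTable, GeneratorConfig, MLPHyper, default_base_learners,
                       develop_stacked_models, generate_cohort, mae)

table, _ = generate_cohort(GeneratorConfig(n=6000, seed=3, cont_subset_fraction=1.0))
train = CohortTable(table.data.iloc[:4500].reset_index(drop=True), table.schema)
test = CohortTable(table.data.iloc[4500:].reset_index(drop=True), table.schema)

hyper = MLPHyper(width=32)
model = develop_stacked_models(train, "continuous", m=2, B=5, seed=7,
                               specs=default_base_learners(mlp_hyper=hyper),
                               meta_hyper=hyper)

print(f"meta-feature rows: {len(model.features.frame)} "
      f"(one averaged out-of-bag prediction pair per outcome-observed patient)")
print(f"meta-linear combination: "
      f"{model.meta_linear.coef.round(3)} + intercept {model.meta_linear.intercept:.3f}")

y_test = test.data[test.schema.y_cont].to_numpy()
preds = model.predict_new(test)
for name in ("ridge", "mlp", "meta_linear", "meta_mlp"):
    print(f"held-out MAE {name:12s}: {mae(y_test, preds[name]).value:.3f}")
print("lower is better; the meta-learners combine both base-learners and "
      "should match or beat the best of them")
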