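"""Severity classification with LASSO and leave-one-patient-out CV.

A synthetic cohort with a 3-SD deceleration-capacity group gap is reduced
to a compact per-visit feature table; the L1-penalized logistic regression
is evaluated by leave-one-patient-out CV (inner 3-fold tuning, 5
repetitions, median-pooled probabilities), and feature popularity counts
how often each feature survives the penalty.
"""

from physiomot import CohortConfig, feature_popularity, generate_cohort, loocv_experiment
from physiomot.pipeline import compact_feature_table

cohort = generate_cohort(CohortConfig(dc_effect=3.0, master_seed=1))
table = compact_feature_table(cohort)
print(f"{len(table.features)} visits x {table.features.shape[1]} features, "
      f"{len(set(table.patient_ids))} patients")

res = loocv_experiment(table, list(table.features.columns), n_reps=5, base_seed=7)
print(f"fitted models: {res.n_models} (5 repetitions x patients)")
print(f"pooled AUC: {res.pooled_auc_value:.3f}")
print("\nfeature popularity (fraction of models with non-zero coefficient):")
print(feature_popularity(res).head(6).to_string())
# The nocturnal deceleration capacity should top the popularity ranking —
# it is the feature the generator links to severity.
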