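"""Train a subtype classifier on one cohort and predict another.

Two cohorts are generated independently, each scored, normalized and
clustered on its own (per-cohort Z; raw values never cross cohorts). A
500-tree Random Forest trained on the first cohort's labels is evaluated on
the second against that cohort's own clustering-derived labels.
"""

import immunotype as it

spec = it.default_paperlike_spec()
train = it.generate_cohort(spec, seed=11)
test = it.generate_cohort(spec, seed=22)

run_train = it.immune_subtypes(train.expression, train.gene_sets,
                               train.immune_set_names)
run_test = it.immune_subtypes(test.expression, test.gene_sets,
                              test.immune_set_names)

model = it.train_subtype_classifier(run_train.features, run_train.assignment,
                                    n_trees=500, seed=17, cohort="train-cohort")
report = it.cross_cohort_predict(model, run_test.features, run_test.assignment)

print(f"cross-cohort accuracy:   {report.accuracy:.3f}")
print(f"cross-cohort weighted F: {report.weighted_f:.3f}")
print("\nconfusion matrix (rows = test cohort's own labels):")
print(report.confusion.to_string())

cv = it.kfold_cv(run_train.features, run_train.assignment, k=10,
                 n_trees=500, seed=17)
print(f"\n10-fold CV accuracy on the training cohort: {cv.accuracy:.3f}")

print("\ntop-5 feature importances (mean impurity decrease):")
print(model.feature_importances.nlargest(5).round(4).to_string())
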