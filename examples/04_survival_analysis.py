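"""Survival differences between subtypes and between immune-score tertiles.

Kaplan-Meier curves with pairwise and three-group log-rank tests between the
immunity subtypes, then the same comparison between the top and bottom thirds
of the immune score.
"""

import immunotype as it

cohort = it.generate_cohort(it.default_paperlike_spec(), seed=7)
run = it.immune_subtypes(cohort.expression, cohort.gene_sets,
                         cohort.immune_set_names)

surv = it.km_logrank(cohort.clinical, run.assignment, endpoint="OS")
print("median overall survival (months) by subtype "
      "(expect immunity-low longest):")
for group, median in surv.median_survival.items():
    print(f"  {group:18s} {median:6.1f}  ({surv.n_events[group]} events)")
print("\npairwise log-rank tests:")
print(surv.pairwise.round(4).to_string(index=False))
print(f"three-group log-rank: chi2 = {surv.k_group_statistic:.2f}, "
      f"p = {surv.k_group_p:.2e}")

# tertile analysis: high vs low third of the immune score
est = it.estimate_scores(cohort.expression,
                         immune_sig=cohort.gene_sets["estimate_immune"],
                         stromal_sig=cohort.gene_sets["estimate_stromal"])
tertiles = it.tertile_split(est.immune_score)
extremes = tertiles[tertiles != "middle"]
t_surv = it.km_logrank(cohort.clinical, extremes, endpoint="OS")
row = t_surv.pairwise.iloc[0]
print(f"\nhigh- vs low-immune-score third: chi2 = {row['chi2']:.2f}, "
      f"p = {row['p']:.2e}")
print("(a high immune score predicting worse survival mirrors the "
      "planted hazard ordering)")
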