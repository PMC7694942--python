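"""Compare genomic features between the immunity subtypes.

Computes per-sample TMB and MATH heterogeneity from the cohort's mutation
table, runs the per-gene mutation-enrichment screen between immunity-high and
immunity-low, and compares arm-level copy-number alteration frequencies.
"""

import immunotype as it

cohort = it.generate_cohort(it.default_paperlike_spec(), seed=7)
run = it.immune_subtypes(cohort.expression, cohort.gene_sets,
                         cohort.immune_set_names)
labels = run.assignment.labels

summary = it.genomic_summary(cohort.mutations, sample_ids=cohort.sample_ids)
by = summary.groupby(labels.loc[summary.index])
print("median TMB by subtype (expect high > low):")
print(by["tmb"].median().round(1).to_string())
print("\nmedian MATH heterogeneity by subtype (expect high < low):")
print(by["math_score"].median().round(1).to_string())

screen = it.mutation_enrichment_screen(cohort.mutations, labels)
hits = screen[screen["passes"]]
print(f"\nmutation screen: {len(hits)} of {screen.attrs['n_tested']} genes pass "
      "(BH-adjusted P < 0.05, odds ratio > 2):")
print(hits[["odds_ratio", "adj_p"]].round(4).to_string())
print(f"planted driver genes: {cohort.planted_mutation_genes}")

arm = it.scna_group_compare(cohort.copy_number_arm, labels)
sig = arm[arm["total_adj_p"] < 0.05]
print(f"\narm-level SCNA: {len(sig)}/{len(arm)} arms differ between "
      "immunity-high and immunity-low (BH-adjusted P < 0.05)")

freq = it.amplification_frequency(cohort.copy_number_gene,
                                  samples=run.assignment.samples("immunity-high"))
print(f"mean gene amplification frequency in immunity-high: {freq.mean():.2f}")
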