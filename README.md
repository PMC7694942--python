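# immunotype

Immunogenomic subtyping of bulk tumor expression cohorts, with gliomas as the
motivating system. Given a genes × samples expression matrix and a collection
of immune-cell signatures, the package:

1. **scores** every signature in every sample with single-sample gene-set
   enrichment (ssGSEA) — a rank-based running sum
   `ES(S) = Σᵢ [P_in(i) − P_out(i)]`, where genes are walked in
   decreasing-expression order, in-set genes accumulate normalized rank
   weights `rᵅ` (default α = 0.25) and out-of-set genes accumulate uniformly;
2. **clusters** samples on their 28 immune-cell enrichment profiles
   (per-feature Z-score clipped to [−3, 3], Ward linkage, three-cluster cut)
   into ordered subtypes **immunity-high / immunity-medium / immunity-low**;
3. **predicts** subtypes across independently normalized cohorts with a
   500-tree Random Forest, reporting accuracy and the support-weighted
   F-score;
4. **quantifies genomic correlates** — tumor mutation burden (TMB), MATH
   intratumor heterogeneity (`100 · MAD/median` of a sample's variant allele
   fractions), gene amplification frequencies, arm/focal copy-number
   comparisons, and a per-gene Fisher + Benjamini-Hochberg mutation-
   enrichment screen (pass: adjusted P < 0.05, odds ratio > 2);
5. **compares clinical outcomes** with Kaplan-Meier curves and pairwise /
   k-group log-rank tests, plus the Mann-Whitney / t / ANOVA / Spearman /
   Fisher battery with BH adjustment.

A seeded synthetic-cohort generator (`immunotype.synthetic_data`) emits every
input format with a planted three-level immunity structure — expression
shifts, subtype-dependent mutation burden and VAF dispersion, copy-number
gain rates, grade/IDH frequencies and survival hazards — so the entire
pipeline is testable end to end without any data download. It is intended
for users analyzing tumor transcriptomes (TSV expression + GMT signatures +
MAF mutations + GISTIC-style calls + clinical tables) who want the
subtype-discovery / cross-cohort-validation workflow as a tested library
rather than a one-off script collection.

## Worked example

```python
import immunotype as it

cohort = it.generate_cohort(it.default_paperlike_spec(), seed=7)
run = it.immune_subtypes(cohort.expression, cohort.gene_sets,
                         cohort.immune_set_names)
est = it.estimate_scores(cohort.expression,
                         immune_sig=cohort.gene_sets["estimate_immune"],
                         stromal_sig=cohort.gene_sets["estimate_stromal"])
print(est.immune_score.groupby(run.assignment.labels).mean().round(2))

surv = it.km_logrank(cohort.clinical, run.assignment, endpoint="OS")
print(surv.median_survival)
```

prints

```
label
immunity-high      341.06
immunity-low        63.07
immunity-medium    266.74

{'immunity-high': 27.4, 'immunity-medium': 20.3, 'immunity-low': 50.5}
```

The immune score orders the recovered subtypes high > medium > low, and
median overall survival (months) is longest in immunity-low — higher immune
infiltration coinciding with worse prognosis, the inverse of what many other
tumor types show. On the same cohort the genomic battery gives median TMB
71 (immunity-high) vs 52 (immunity-low), median MATH 29.2 vs 39.6, and the
mutation screen recovers all six planted driver genes
(`examples/03_genomic_comparisons.py`).

The `examples/` directory holds one short narrative script per capability
(subtyping, cross-cohort prediction, genomic comparisons, survival); each
generates its own input and prints what the numbers mean. A thin CLI mirrors
the same steps for shell use:

```bash
immunotype simulate --seed 7 -o cohort/
immunotype score --expr cohort/expression.tsv --gmt cohort/gene_sets.gmt -o scores.tsv
immunotype cluster --scores scores.tsv -o subtypes.tsv
immunotype survival --clinical cohort/clinical.tsv --subtypes subtypes.tsv -o surv.json
```

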