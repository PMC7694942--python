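# Methods

`immunotype` implements an immunogenomic subtyping workflow for bulk tumor
expression cohorts, with gliomas as the motivating system. This note records
the models, conventions, parameter choices and known limitations behind each
stage.

## Single-sample enrichment scoring (ssGSEA)

For one sample, genes are ranked by expression (average ranks on ties, the
largest value receiving rank *N*) and walked in decreasing order, ties broken
by input gene order so the walk is deterministic. The enrichment score of a
gene set *S* is

ES(S) = Σᵢ [ P_in(i) − P_out(i) ],

where the sum runs over all *N* walk positions, P_in accumulates in-set rank
weights |r|^α normalized by their total, and P_out accumulates out-of-set
genes uniformly. The statistic is the integrated difference between the two
empirical CDFs, so it grows with both the coherence and the extremity of the
set's placement in the sample's ranking. Because only within-sample ranks
enter, the score is invariant to any strictly monotone transform of a
sample's expression vector, and cross-cohort comparisons should always score
each cohort separately rather than pool raw values across platforms.

Parameters:

* `alpha` (default **0.25**) — the rank-weighting exponent of the original
  single-sample formulation. `alpha = 0` reduces to the unweighted
  Kolmogorov running sum.
* `normalize` (default **True**) — rescales all scores in a collection to
  [0, 1] by the global `(x − min)/(max − min)` over every set and sample.
  This variant (rather than dividing by the range alone) is used so that
  normalized scores have a fixed interval interpretation. Clustering and
  classification are unaffected by the choice because the downstream Z-scoring
  is affine-invariant; the flag matters only when raw score magnitudes are
  reported.

A set with no genes in the matrix is flagged missing (NaN scores, warning); a
set covering every gene is an error since the out-of-set CDF is undefined.

## Immune score, stromal score, tumor purity

Immune and stromal content are raw ssGSEA scores of an immune and a stromal
marker signature; their sum anchors the purity estimate

purity = cos(0.6049872018 + 0.0001467884 · (immune + stromal)),

the published calibration of the signature-based purity method. Purity is
monotonically decreasing in the combined score over the working range and is
reported both raw (in [−1, 1]) and clipped to [0, 1]. The packaged signature
GMT is a **synthetic stand-in** assembled from canonical immune (T/B/NK,
cytolytic, antigen-presentation) and stromal (collagen, matrix-remodeling,
fibroblast) marker genes — it is not the published 141-gene pair, which is
why the file and its loader are labelled synthetic; analyses of real cohorts
should pass the published signatures explicitly. The score scaling constant
shipped with the package data is 1.0, i.e. scores are reported on the raw
running-sum scale.

## Signature ratios

The immune-promoting / immune-inhibiting balance of a sample (e.g. CD8+ T
cells vs regulatory T cells, M1 vs M2 macrophages) is summarized as
`log2(mean_a) − log2(mean_b)`, the log2 of the quotient of mean **linear**
expression over the two marker sets. A log2-declared matrix is exponentiated
before averaging; a non-positive mean aborts with instructions to use the
linear path, rather than silently producing NaN. The statistic is
antisymmetric by construction.

## Subtyping

Samples are clustered on their 28 immune-cell enrichment profiles after
per-feature Z-scoring (sample standard deviation, n−1 denominator) and
clipping to [−3, 3]. The clip bounds the influence of outlying samples and
makes the clustering space identical to the classifier's feature space.
Zero-variance features are dropped with a warning; Z of a single sample is
undefined and an error.

Clustering is agglomerative with **Ward linkage on Euclidean distance**
(complete/average exposed by flag), cut at k = 3. Ward is the default because
it favors compact, balanced clusters, which is the regime the three-level
immunity structure occupies; k is fixed at 3 by design, with no automatic
selection. Clusters are ordered by their mean feature Z and labelled
`immunity-high` / `immunity-medium` / `immunity-low`; using the internal mean-Z
key avoids making the label order circularly dependent on the immune-score
signature, and the immune score reproduces the same ordering on every cohort
where recovery succeeds (this is asserted in the test suite). Ties in the
ordering key break by cluster id, so assignment is deterministic and
permutation-invariant.

`tertile_split` ranks a per-sample score and assigns the top ⌈n/3⌉ to the
high third and the bottom ⌈n/3⌉ to the low third, remainder in the middle;
boundary ties resolve by stable input order with a warning.

## Cross-cohort prediction

A Random Forest with **500 trees** (other hyperparameters at scikit-learn
defaults: sqrt-feature subsampling, unlimited depth) is trained on one
cohort's Z-clipped features against its clustering-derived labels. Test
cohorts are normalized **within themselves** before prediction — each cohort
is clustered and Z-scored independently, so transfer happens in the
standardized space, never on raw cross-platform values — and predictions are
scored against the test cohort's own clustering labels. Reported metrics:
overall accuracy and the class-support-weighted mean of per-class F1, plus
per-class precision/recall/F1, the confusion matrix, and mean-impurity-
decrease importances. Cross-validation uses stratified folds (falling back to
plain folds with a warning when a class is smaller than k) and scores pooled
out-of-fold predictions once, rather than averaging per-fold metrics.

## Genomic features

* **TMB** is the total count of a sample's somatic mutation records, all
  variant classes included (silent and indels count); a
  `nonsynonymous_only` flag restricts to protein-altering classes. Duplicate
  identical records count twice unless `dedupe` is set.
* **MATH** is `100 · MAD / median` over a sample's variant allele fractions,
  with MAD = 1.4826 · median(|v − median|). All VAF-defined variants enter
  (no depth filter by default; `min_depth` available). Fewer than two usable
  VAFs, or a zero median, yield a missing value with a stated reason. The
  ratio is invariant to positive rescaling of the VAFs.
* **Amplification frequency** of a gene in a sample group is the fraction of
  samples with a thresholded call ≥ +1.
* **SCNA group comparison** tabulates amplification / deletion / total-
  alteration frequencies per feature (arm or gene) in two groups, with a
  two-sided Fisher exact P per category and BH adjustment across features.
  Real-valued focal levels are compared via each sample's mean |level|
  (and the amp/del components) with Mann-Whitney tests. Thresholded inputs
  are consumed as produced by external segmentation tools; segmentation
  itself is out of scope.
* **Mutation-enrichment screen**: genes with ≥ `min_count` (default 3)
  mutated samples enter a per-gene 2×2 Fisher exact test between two
  subtypes. The odds ratio is reported with the Haldane–Anscombe 0.5
  correction when a cell is zero (the P value uses the uncorrected table),
  P values are BH-adjusted across tested genes, and a gene passes when
  adjusted P < 0.05 **and** odds ratio > 2. The `min_count` default avoids
  degenerate tables; under permuted labels the mean passing fraction is
  calibrated well below 5% (asserted in the acceptance suite).

## Statistics and survival

Mann-Whitney U uses exact enumeration when the combined n ≤ 12 with no ties,
otherwise the normal approximation with tie and continuity correction; the
method used is recorded on the result. One-tailed comparisons always declare
their direction from the a-priori subtype ordering (high > medium > low).
One-way ANOVA special-cases zero within-group variance (F = 0, P = 1 when
means are also equal; F = ∞, P = 0 otherwise). Spearman correlation uses
average ranks and the t-approximation for P. BH adjustment is the standard
step-up procedure, order-preserving and capped at 1.

Survival curves are Kaplan-Meier product-limit estimates per group; with no
censoring they coincide with the empirical survival function exactly. Both
every pairwise two-group log-rank test (1 df) and the k-group test are
reported, because pairwise statements (e.g. high vs low) and the joint
three-subtype comparison answer different questions; no multiplicity
adjustment is applied across the three pairs unless requested. Survival time
units pass through from the clinical table unchanged. Groups with no
observations are excluded with a warning; a pair with no events reports NaN
rather than a fabricated statistic.

## Synthetic cohorts

The generator plants a three-level immunity structure in every input type
from a single seeded `numpy` generator (no global state):

* **Expression** — baseline Normal(0, σ) on log2 scale (σ = 1), plus a
  stratum shift δ on every gene of the immune blocks, with
  δ = (3.0, 1.5, 0.0) noise-sd units for (high, medium, low): a spacing of
  1.5 sd between adjacent strata. The 28 immune-cell sets (15 genes each,
  disjoint by default; an overlap fraction exists because real signatures
  overlap) shift at 1.0·δ; an immune and a stromal scoring signature, CD8 /
  Treg and M1 / M2 marker sets (asymmetric multipliers 1.2/0.6 and 1.1/0.7,
  so promoting/inhibiting ratios rise with immunity), stemness and EMT sets
  (0.8·δ), and a single PD-L1-like marker gene are laid out alongside
  background genes, 1 200 genes in total. A constant +8 keeps log2 values
  positive for the linear-scale ratio path.
* **Mutations** — per-sample counts are Poisson with stratum means
  (70, 60, 52), gene symbols drawn from a Zipf-weighted background catalog of
  60 genes; six planted driver genes mutate through separate stratum
  Bernoullis (0.45, 0.20, 0.05) so the enrichment screen has a clean truth.
  VAFs are Beta draws with stratum parameters chosen so the dispersion
  (CV ≈ MATH/100 for these near-symmetric Betas) targets MATH medians near
  29 (high), 33 (medium) and 38 (low) — tighter allele-frequency
  distributions in the high-immunity stratum. Read counts realize each VAF
  at a depth of 80–120 by rounding, preserving the Beta dispersion rather
  than inflating it with binomial resampling.
* **Copy number** — gene-level gains on a 40-gene cytokine-like panel with
  stratum probabilities (0.40, 0.25, 0.12); arm-level gains (0.50, 0.35,
  0.20) and losses (0.45, 0.30, 0.18) over 14 arms, magnitudes ±1/±2 at
  70/30.
* **Clinical** — overall survival is exponential with stratum hazards
  (0.0495, 0.0347, 0.0173) per month (medians ≈ 14 / 20 / 40 months, worse
  survival with higher immunity); disease-free survival uses a 1.4× hazard.
  Censoring marks each sample censored with probability 0.3 and rescales its
  time by a Uniform(0, 1) factor, giving an exact expected censoring
  fraction. Grade IV occurs with probability (0.62, 0.40, 0.15) — implying a
  high-vs-low odds ratio near 9 — and IDH-mutant status with (0.20, 0.45,
  0.70), so IDH mutation anti-correlates with immunity.

Sample sizes default to 60 per stratum. These defaults are the package's
study conditions; the acceptance checks run against them unmodified.

**What the generator does not emulate:** platform and batch effects,
correlated co-expression structure within and between signatures, subclonal
copy-number segments, mutation signatures, covariate-dependent censoring, and
the messy partial overlap of real marker-gene lists. Tests passing on these
cohorts therefore demonstrate that the machinery is correct and that the
planted effect sizes are recoverable — not that real glioma cohorts will
separate this cleanly; real-data accuracies will be lower and cluster
boundaries fuzzier.

## Numerical choices and degenerate inputs

* ssGSEA tie handling: average ranks for weights, input order for the walk.
* Z-scoring uses the sample (n−1) standard deviation.
* Range normalization with a degenerate (max = min) score range returns zeros
  with a warning instead of dividing by zero.
* The dendrogram cut asserts that k non-empty clusters were produced.
* Odds ratios with a zero cell use the 0.5 correction for reporting only.
* All stochastic APIs take explicit integer seeds; identical input and seed
  give byte-identical outputs (asserted for the generator's file writers).

## Problem sizes used in the validation suite

Module tests run on scaled-down cohorts (20 samples/stratum, 700 genes,
8-gene sets) chosen to exercise every code path quickly; the acceptance
checks use the full default conditions (60/stratum, 1 200 genes, 50 and 20
replicates for recovery and direction checks, 200 replicates/permutations
for power and calibration). These sizes are the package's validation design.

## Known limitations

* The shipped scoring signatures are synthetic stand-ins (see above).
* The hierarchical-clustering linkage and the decision to cluster on clipped
  Z scores are package choices; alternatives are flag-selectable rather than
  silently switched, and results on real cohorts can depend on them.
* Prediction quality is defined against clustering-derived labels, so label
  noise in a test cohort bounds achievable "accuracy".
* Cox models, competing risks and interval censoring are out of scope;
  log-rank and KM are the only survival tools provided.
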