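"""Genomic feature quantification and between-subtype comparisons.

* TMB — tumor mutation burden, the total somatic mutation count of a sample
  (all variant classes, including silent and indels, unless
  ``nonsynonymous_only`` is set).
* MATH — mutant-allele tumor heterogeneity, ``100 * MAD / median`` of a
  sample's variant allele fractions with the normal-consistent MAD
  (``1.4826 * median(|v - median|)``); a proxy for intratumor heterogeneity.
* Gene amplification frequency — fraction of samples with a copy-number gain
  (thresholded call >= +1) in a gene.
* Arm/gene-level SCNA group comparison and the per-gene mutation-enrichment
  screen between two subtypes (Fisher exact + Benjamini-Hochberg, pass when
  adjusted P < 0.05 and odds ratio > 2).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import CopyNumberTable, MutationTable
from .stats_survival import bh_adjust, mann_whitney
from .subtyping import SubtypeAssignment

__all__ = [
    "compute_tmb",
    "compute_math",
    "math_scores",
    "genomic_summary",
    "amplification_frequency",
    "scna_group_compare",
    "focal_level_compare",
    "mutation_enrichment_screen",
]

MAD_CONSTANT = 1.4826

NONSYNONYMOUS_CLASSES = {
    "Missense_Mutation", "Nonsense_Mutation", "Nonstop_Mutation",
    "Frame_Shift_Del", "Frame_Shift_Ins", "In_Frame_Del", "In_Frame_Ins",
    "Splice_Site", "Translation_Start_Site",
}


def _groups(grouping: SubtypeAssignment | pd.Series) -> pd.Series:
    return grouping.labels if isinstance(grouping, SubtypeAssignment) else grouping


def compute_tmb(muts: MutationTable, sample_ids: list[str] | None = None,
                dedupe: bool = False, nonsynonymous_only: bool = False) -> pd.Series:
    """Per-sample somatic mutation count.

    Duplicated identical records are counted twice unless ``dedupe``. Samples
    absent from the table get 0 only when enumerated in ``sample_ids``.
    """
    rec = muts.records
    if nonsynonymous_only:
        rec = rec[rec["variant_class"].isin(NONSYNONYMOUS_CLASSES)]
    if dedupe:
        rec = rec.drop_duplicates(
            subset=["sample_id", "gene", "variant_class", "ref_count", "alt_count"])
    tmb = rec.groupby("sample_id").size()
    if sample_ids is not None:
        tmb = tmb.reindex(sample_ids, fill_value=0)
    tmb.name = "tmb"
    tmb.index.name = "sample_id"
    return tmb.astype(int)


def _math_from_vafs(vafs: np.ndarray) -> float:
    med = float(np.median(vafs))
    if med == 0:
        return np.nan
    mad = MAD_CONSTANT * float(np.median(np.abs(vafs - med)))
    return 100.0 * mad / med


def compute_math(muts: MutationTable, sample: str, min_depth: int = 0) -> float:
    """MATH score of one sample: ``100 * MAD(VAFs) / median(VAFs)``.

    Uses all VAF-defined variants (no depth filter by default). Returns NaN
    with a warning when fewer than 2 usable VAFs exist or the median VAF is 0.
    """
    rec = muts.for_sample(sample)
    if min_depth > 0:
        rec = rec[rec["ref_count"] + rec["alt_count"] >= min_depth]
    vafs = rec["vaf"].dropna().to_numpy(float)
    if len(vafs) < 2:
        warnings.warn(f"sample {sample}: <2 usable VAFs, MATH undefined")
        return np.nan
    score = _math_from_vafs(vafs)
    if np.isnan(score):
        warnings.warn(f"sample {sample}: median VAF is 0, MATH undefined")
    return score


def math_scores(muts: MutationTable, sample_ids: list[str] | None = None,
                min_depth: int = 0) -> pd.Series:
    """MATH score for every sample (NaN where undefined)."""
    samples = sample_ids if sample_ids is not None else muts.sample_ids
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out = pd.Series({s: compute_math(muts, s, min_depth=min_depth) for s in samples},
                        name="math_score")
    out.index.name = "sample_id"
    return out


def genomic_summary(muts: MutationTable,
                    sample_ids: list[str] | None = None) -> pd.DataFrame:
    """Per-sample TMB, MATH score, and VAF count in one table."""
    samples = sample_ids if sample_ids is not None else muts.sample_ids
    tmb = compute_tmb(muts, sample_ids=samples)
    math = math_scores(muts, sample_ids=samples)
    n_vaf = muts.records.dropna(subset=["vaf"]).groupby("sample_id").size() \
        .reindex(samples, fill_value=0)
    return pd.DataFrame({"tmb": tmb, "math_score": math,
                         "n_vaf_used": n_vaf.astype(int)})


def amplification_frequency(cn: CopyNumberTable, genes: list[str] | None = None,
                            samples: list[str] | None = None) -> pd.Series:
    """Fraction of samples with a copy-number gain (call >= +1) per gene."""
    if cn.level != "gene":
        raise ValueError("amplification_frequency needs a gene-level table")
    calls = cn.calls
    if samples is not None:
        calls = calls[samples]
    if genes is not None:
        missing = [g for g in genes if g not in calls.index]
        if missing:
            warnings.warn(f"genes absent from copy-number table: {missing}")
        calls = calls.reindex(genes)
    freq = (calls >= 1).sum(axis=1) / calls.shape[1]
    freq[calls.isna().all(axis=1)] = np.nan
    freq.name = "amplification_frequency"
    return freq


def _fisher_2x2(k_a: int, n_a: int, k_b: int, n_b: int) -> float:
    table = [[k_a, n_a - k_a], [k_b, n_b - k_b]]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def scna_group_compare(cn: CopyNumberTable,
                       grouping: SubtypeAssignment | pd.Series,
                       group_a: str = "immunity-high",
                       group_b: str = "immunity-low") -> pd.DataFrame:
    """Compare per-feature alteration frequencies between two sample groups.

    For each feature (arm or gene) reports amplification (call >= +1),
    deletion (call <= -1) and total-alteration (call != 0) frequencies in each
    group, a two-sided Fisher exact P per category, and Benjamini-Hochberg
    adjusted P across features within each category.
    """
    labels = _groups(grouping)
    samples_a = [s for s in cn.sample_ids if labels.get(s) == group_a]
    samples_b = [s for s in cn.sample_ids if labels.get(s) == group_b]
    if not samples_a or not samples_b:
        raise ValueError(f"empty group ({group_a}: {len(samples_a)}, "
                         f"{group_b}: {len(samples_b)})")
    calls_a = cn.calls[samples_a].to_numpy()
    calls_b = cn.calls[samples_b].to_numpy()
    n_a, n_b = len(samples_a), len(samples_b)

    rows = {}
    for cat, pred in (("amp", lambda c: c >= 1), ("del", lambda c: c <= -1),
                      ("total", lambda c: c != 0)):
        k_a = pred(calls_a).sum(axis=1)
        k_b = pred(calls_b).sum(axis=1)
        rows[f"{cat}_freq_{group_a}"] = k_a / n_a
        rows[f"{cat}_freq_{group_b}"] = k_b / n_b
        pvals = [_fisher_2x2(int(ka), n_a, int(kb), n_b) for ka, kb in zip(k_a, k_b)]
        rows[f"{cat}_fisher_p"] = pvals
        rows[f"{cat}_adj_p"] = bh_adjust(pvals)
    out = pd.DataFrame(rows, index=cn.calls.index.rename("feature"))
    out.attrs["groups"] = (group_a, group_b)
    out.attrs["n_per_group"] = (n_a, n_b)
    return out


def focal_level_compare(levels: pd.DataFrame,
                        grouping: SubtypeAssignment | pd.Series,
                        group_a: str = "immunity-high",
                        group_b: str = "immunity-low") -> pd.DataFrame:
    """Compare real-valued focal SCNA levels (features x samples) between groups.

    Each sample is summarized by its mean amplification level (positive
    entries), mean deletion magnitude (|negative entries|) and mean |level|;
    each summary is compared by a two-sided Mann-Whitney U test.
    """
    labels = _groups(grouping)
    cols_a = [s for s in levels.columns if labels.get(s) == group_a]
    cols_b = [s for s in levels.columns if labels.get(s) == group_b]
    if not cols_a or not cols_b:
        raise ValueError("empty group in focal-level comparison")
    vals = levels.to_numpy(float)
    summaries = {
        "amp": np.where(vals > 0, vals, 0.0).mean(axis=0),
        "del": np.where(vals < 0, -vals, 0.0).mean(axis=0),
        "total": np.abs(vals).mean(axis=0),
    }
    idx_a = [levels.columns.get_loc(s) for s in cols_a]
    idx_b = [levels.columns.get_loc(s) for s in cols_b]
    rows = []
    for cat, per_sample in summaries.items():
        res = mann_whitney(per_sample[idx_a], per_sample[idx_b], tail="two-sided")
        rows.append({"category": cat,
                     f"mean_{group_a}": per_sample[idx_a].mean(),
                     f"mean_{group_b}": per_sample[idx_b].mean(),
                     "p": res.p})
    return pd.DataFrame(rows).set_index("category")


def mutation_enrichment_screen(muts: MutationTable,
                               grouping: SubtypeAssignment | pd.Series,
                               group_a: str = "immunity-high",
                               group_b: str = "immunity-low",
                               min_count: int = 3) -> pd.DataFrame:
    """Per-gene differential mutation screen between two subtypes.

    Each gene with >= ``min_count`` mutated samples overall enters a 2x2
    Fisher exact test (mutated / not x group). The odds ratio is reported with
    the Haldane-Anscombe 0.5 correction when any cell is 0 (the P value uses
    the uncorrected table). P values are Benjamini-Hochberg adjusted across
    tested genes; ``passes`` is True when adjusted P < 0.05 AND odds ratio > 2
    in the ``group_a`` direction.
    """
    labels = _groups(grouping)
    samples_a = set(labels.index[labels == group_a])
    samples_b = set(labels.index[labels == group_b])
    if not samples_a or not samples_b:
        raise ValueError("both groups must be non-empty")
    rec = muts.records[muts.records["sample_id"].isin(samples_a | samples_b)]
    mutated = rec.groupby("gene")["sample_id"].agg(set)

    n_a, n_b = len(samples_a), len(samples_b)
    rows = []
    for gene, carriers in mutated.items():
        k_a = len(carriers & samples_a)
        k_b = len(carriers & samples_b)
        if k_a + k_b < min_count:
            continue
        table = np.array([[k_a, n_a - k_a], [k_b, n_b - k_b]], float)
        p = float(stats.fisher_exact(table, alternative="two-sided")[1])
        if (table == 0).any():
            table = table + 0.5
        odds = float(table[0, 0] * table[1, 1] / (table[0, 1] * table[1, 0]))
        rows.append({"gene": gene, f"mutated_{group_a}": k_a,
                     f"mutated_{group_b}": k_b,
                     f"unmutated_{group_a}": n_a - k_a,
                     f"unmutated_{group_b}": n_b - k_b,
                     "odds_ratio": odds, "fisher_p": p,
                     "direction": group_a if k_a / n_a >= k_b / n_b else group_b})
    if not rows:
        out = pd.DataFrame(columns=["gene", "odds_ratio", "fisher_p", "adj_p",
                                    "passes"]).set_index("gene")
        out.attrs["n_tested"] = 0
        return out
    out = pd.DataFrame(rows).set_index("gene")
    out["adj_p"] = bh_adjust(out["fisher_p"].to_numpy())
    out["passes"] = (out["adj_p"] < 0.05) & (out["odds_ratio"] > 2)
    out.attrs["n_tested"] = len(out)
    out.attrs["groups"] = (group_a, group_b)
    return out.sort_values("fisher_p")
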