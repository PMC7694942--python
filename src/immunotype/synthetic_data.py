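"""Synthetic glioma-like cohorts with planted three-level immunity structure.

:func:`generate_cohort` emits every input the pipeline consumes — expression,
gene sets, mutations (MAF-style), gene- and arm-level copy-number calls, and a
clinical table — from a single seeded generator, with the ground-truth stratum
of every sample stored separately from the analysis inputs.

The planted structure mirrors the qualitative glioma findings the pipeline is
meant to recover: three immunity strata (high / medium / low) that shift the
expression of immune-signature genes, with the high-immunity stratum carrying
higher mutation burden, tighter VAF distributions (lower MATH), more frequent
copy-number gains, more grade-IV / fewer IDH-mutant tumors, and worse survival.

:func:`default_paperlike_spec` encodes the default study conditions:
stratum expression shifts delta = (3.0, 1.5, 0.0) noise-sd units, 60 samples
per stratum, TMB Poisson means 70/60/52, VAF Beta dispersions targeting MATH
medians near 29 (high) vs 38 (low), grade-IV probabilities 0.62/0.40/0.15
(odds ratio ~9 between high and low), IDH-mutant probabilities 0.20/0.45/0.70,
exponential overall-survival hazards giving median ~14/20/40 months, and 30%
censoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (ClinicalTable, CopyNumberTable, ExpressionMatrix,
                         GeneSetCollection, MutationTable)

__all__ = ["CohortSpec", "SyntheticCohort", "default_paperlike_spec",
           "generate_cohort", "write_cohort"]

STRATA = ("high", "medium", "low")

DEFAULT_ARMS = ("1p", "1q", "7p", "7q", "9p", "9q", "10p", "10q", "19p", "19q",
                "13q", "14q", "20p", "20q")

VARIANT_CLASSES = ("Missense_Mutation", "Nonsense_Mutation", "Silent",
                   "Frame_Shift_Del", "Frame_Shift_Ins", "Splice_Site")
VARIANT_CLASS_PROBS = (0.58, 0.08, 0.22, 0.05, 0.04, 0.03)


@dataclass
class CohortSpec:
    """All knobs of the cohort generator; tuples are ordered (high, medium, low)."""

    n_genes: int = 1200
    n_per_stratum: tuple[int, int, int] = (60, 60, 60)
    n_immune_sets: int = 28
    immune_set_size: int = 15
    immune_set_overlap: float = 0.0      # fraction of set genes drawn from a shared pool
    delta: tuple[float, float, float] = (3.0, 1.5, 0.0)   # expression shift, noise-sd units
    noise_sd: float = 1.0
    tmb_means: tuple[float, float, float] = (70.0, 60.0, 52.0)
    vaf_beta: tuple[tuple[float, float], ...] = ((7.4, 13.8), (5.6, 10.4), (4.1, 7.6))
    n_mutation_genes: int = 60
    n_planted_genes: int = 6
    planted_mut_prob: tuple[float, float, float] = (0.45, 0.20, 0.05)
    arm_names: tuple[str, ...] = DEFAULT_ARMS
    arm_gain_prob: tuple[float, float, float] = (0.50, 0.35, 0.20)
    arm_loss_prob: tuple[float, float, float] = (0.45, 0.30, 0.18)
    cn_gene_gain_prob: tuple[float, float, float] = (0.40, 0.25, 0.12)
    n_cn_genes: int = 40
    os_hazard: tuple[float, float, float] = (0.0495, 0.0347, 0.0173)  # per month
    dfs_hazard_ratio: float = 1.4
    censoring_fraction: float = 0.30
    grade4_prob: tuple[float, float, float] = (0.62, 0.40, 0.15)
    idh_mutant_prob: tuple[float, float, float] = (0.20, 0.45, 0.70)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.delta[0] > self.delta[1] > self.delta[2]):
            raise ValueError("delta must be strictly decreasing high > medium > low")
        for name in ("planted_mut_prob", "arm_gain_prob", "arm_loss_prob",
                     "cn_gene_gain_prob", "grade4_prob", "idh_mutant_prob"):
            vals = getattr(self, name)
            if any(not (0.0 <= v <= 1.0) for v in vals):
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0.0 <= self.censoring_fraction <= 1.0:
            raise ValueError("censoring_fraction must lie in [0, 1]")
        if any(h <= 0 for h in self.os_hazard):
            raise ValueError("hazards must be positive")


@dataclass
class SyntheticCohort:
    """A complete synthetic cohort plus ground truth (kept out of the inputs)."""

    expression: ExpressionMatrix
    gene_sets: GeneSetCollection
    mutations: MutationTable
    copy_number_gene: CopyNumberTable
    copy_number_arm: CopyNumberTable
    clinical: ClinicalTable
    strata: pd.Series                 # ground-truth stratum per sample
    immune_set_names: list[str]       # the 28 clustering features
    pdl1_gene: str
    planted_mutation_genes: list[str]
    spec: CohortSpec = field(repr=False, default=None)

    @property
    def sample_ids(self) -> list[str]:
        return self.expression.sample_ids


def default_paperlike_spec(**overrides) -> CohortSpec:
    """The default study conditions (see module docstring); overridable per field."""
    return CohortSpec(**overrides)


def _immune_gene_blocks(spec: CohortSpec) -> dict[str, list[str]]:
    """Lay out named gene blocks; the 28 immune sets are disjoint by default."""
    blocks: dict[str, list[str]] = {}
    for k in range(spec.n_immune_sets):
        name = f"immune_cell_{k + 1:02d}"
        blocks[name] = [f"IMM{k + 1:02d}_{i + 1:03d}" for i in range(spec.immune_set_size)]
    blocks["estimate_immune"] = [f"ESTIMM_{i + 1:03d}" for i in range(30)]
    blocks["estimate_stromal"] = [f"ESTSTR_{i + 1:03d}" for i in range(30)]
    blocks["sig_cd8"] = [f"CD8M_{i + 1:02d}" for i in range(12)]
    blocks["sig_treg"] = [f"TREGM_{i + 1:02d}" for i in range(12)]
    blocks["sig_m1"] = [f"M1M_{i + 1:02d}" for i in range(12)]
    blocks["sig_m2"] = [f"M2M_{i + 1:02d}" for i in range(12)]
    blocks["stemness"] = [f"STEM_{i + 1:02d}" for i in range(20)]
    blocks["emt"] = [f"EMT_{i + 1:02d}" for i in range(20)]
    return blocks


# multiplier on the stratum shift per block; stromal genes carry no immunity signal
_BLOCK_SHIFT = {"estimate_immune": 1.0, "estimate_stromal": 0.0,
                "sig_cd8": 1.2, "sig_treg": 0.6, "sig_m1": 1.1, "sig_m2": 0.7,
                "stemness": 0.8, "emt": 0.8}


def generate_cohort(spec: CohortSpec, seed: int | None = None) -> SyntheticCohort:
    """Generate a full cohort from ``spec`` (seed overrides ``spec.seed``).

    Expression is baseline Normal(0, noise_sd) on log2 scale plus the stratum
    shift on immune-block genes; mutations get Poisson counts with Beta VAFs
    realized as integer read counts; copy-number calls are Bernoulli gains and
    losses; survival is exponential with stratum hazards and uniform censoring.
    Fully reproducible from the seed.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    blocks = _immune_gene_blocks(spec)
    immune_names = [n for n in blocks if n.startswith("immune_cell_")]

    if spec.immune_set_overlap > 0.0:
        pool = [g for n in immune_names for g in blocks[n]]
        for name in immune_names:
            genes = blocks[name]
            n_shared = int(round(spec.immune_set_overlap * len(genes)))
            if n_shared:
                shared = list(rng.choice(pool, size=n_shared, replace=False))
                blocks[name] = list(dict.fromkeys(shared + genes))[:len(genes)]

    pdl1_gene = "PDL1_MARKER"
    # genes may belong to several sets when overlap > 0; the universe is unique
    structured = list(dict.fromkeys(
        [g for genes in blocks.values() for g in genes] + [pdl1_gene]))
    n_background = spec.n_genes - len(structured)
    if n_background < 0:
        raise ValueError(
            f"gene sets need {len(structured)} genes but n_genes={spec.n_genes}")
    background = [f"BG_{i + 1:04d}" for i in range(n_background)]
    gene_ids = structured + background

    n_samples = sum(spec.n_per_stratum)
    sample_ids = [f"S{i + 1:04d}" for i in range(n_samples)]
    strata = np.repeat(STRATA, spec.n_per_stratum)

    # --- expression ---------------------------------------------------------
    values = rng.normal(0.0, spec.noise_sd, size=(len(gene_ids), n_samples))
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    delta_of = dict(zip(STRATA, spec.delta))
    shift_rows: dict[str, float] = {}
    for name, genes in blocks.items():
        mult = _BLOCK_SHIFT.get(name, 1.0)  # the 28 immune sets shift at 1.0
        for g in genes:
            shift_rows[g] = max(shift_rows.get(g, 0.0), mult)
    shift_rows[pdl1_gene] = 1.0
    for g, mult in shift_rows.items():
        row = gene_pos[g]
        for s, d in delta_of.items():
            values[row, strata == s] += mult * d * spec.noise_sd
    # keep log2 values positive enough for the linear-scale ratio path
    values += 8.0

    expression = ExpressionMatrix(
        values=pd.DataFrame(values, index=pd.Index(gene_ids, name="gene_id"),
                            columns=sample_ids),
        is_log2=True)

    gene_sets = GeneSetCollection(
        sets={name: list(genes) for name, genes in blocks.items()},
        descriptions={name: "synthetic planted signature" for name in blocks})

    # --- mutations ----------------------------------------------------------
    # background catalog carries the Poisson burden; planted genes mutate only
    # through the stratum-dependent Bernoulli so the group contrast is clean
    catalog = [f"MUT_{i + 1:03d}" for i in range(spec.n_mutation_genes)]
    planted = [f"DRV_{i + 1:02d}" for i in range(spec.n_planted_genes)]
    weights = 1.0 / np.arange(1, spec.n_mutation_genes + 1)  # Zipf-ish recurrence
    weights /= weights.sum()
    planted_p = dict(zip(STRATA, spec.planted_mut_prob))
    beta_of = dict(zip(STRATA, spec.vaf_beta))
    tmb_of = dict(zip(STRATA, spec.tmb_means))

    rec_sample, rec_gene, rec_class, rec_ref, rec_alt = [], [], [], [], []

    def _add_record(sample: str, gene: str, a: float, b: float) -> None:
        vaf = rng.beta(a, b)
        depth = int(rng.integers(80, 120))
        alt = int(round(vaf * depth))
        rec_sample.append(sample)
        rec_gene.append(gene)
        rec_class.append(rng.choice(VARIANT_CLASSES, p=VARIANT_CLASS_PROBS))
        rec_ref.append(depth - alt)
        rec_alt.append(alt)

    for sample, stratum in zip(sample_ids, strata):
        a, b = beta_of[stratum]
        n_mut = rng.poisson(tmb_of[stratum])
        for gene in rng.choice(catalog, size=n_mut, p=weights):
            _add_record(sample, gene, a, b)
        for gene in planted:  # extra planted-gene mutations, stratum-dependent
            if rng.random() < planted_p[stratum]:
                _add_record(sample, gene, a, b)

    mutations = MutationTable(records=pd.DataFrame({
        "sample_id": rec_sample, "gene": rec_gene, "variant_class": rec_class,
        "ref_count": rec_ref, "alt_count": rec_alt}))

    # --- copy number --------------------------------------------------------
    def _calls(features: list[str], p_gain: dict, p_loss: dict | None) -> pd.DataFrame:
        calls = np.zeros((len(features), n_samples), dtype=int)
        for j, stratum in enumerate(strata):
            gains = rng.random(len(features)) < p_gain[stratum]
            calls[gains, j] = rng.choice([1, 2], size=int(gains.sum()), p=[0.7, 0.3])
            if p_loss is not None:
                losses = (rng.random(len(features)) < p_loss[stratum]) & ~gains
                calls[losses, j] = rng.choice([-1, -2], size=int(losses.sum()),
                                              p=[0.7, 0.3])
        return pd.DataFrame(calls, index=pd.Index(features, name="feature_id"),
                            columns=sample_ids)

    cn_genes = [f"CYTO_{i + 1:03d}" for i in range(spec.n_cn_genes)]
    copy_number_gene = CopyNumberTable(
        level="gene",
        calls=_calls(cn_genes, dict(zip(STRATA, spec.cn_gene_gain_prob)), None))
    copy_number_arm = CopyNumberTable(
        level="arm",
        calls=_calls(list(spec.arm_names), dict(zip(STRATA, spec.arm_gain_prob)),
                     dict(zip(STRATA, spec.arm_loss_prob))))

    # --- clinical -----------------------------------------------------------
    os_h = dict(zip(STRATA, spec.os_hazard))

    def _survival(hazards: dict) -> tuple[np.ndarray, np.ndarray]:
        times = np.array([rng.exponential(1.0 / hazards[s]) for s in strata])
        status = np.ones(n_samples, dtype=int)
        censored = rng.random(n_samples) < spec.censoring_fraction
        times[censored] *= rng.random(int(censored.sum()))  # uniform early stop
        status[censored] = 0
        return np.round(times, 2), status

    os_time, os_status = _survival(os_h)
    dfs_time, dfs_status = _survival(
        {s: h * spec.dfs_hazard_ratio for s, h in os_h.items()})

    grade4_p = dict(zip(STRATA, spec.grade4_prob))
    idh_p = dict(zip(STRATA, spec.idh_mutant_prob))
    grade = np.where([rng.random() < grade4_p[s] for s in strata], "IV",
                     rng.choice(["II", "III"], size=n_samples))
    idh = np.where([rng.random() < idh_p[s] for s in strata], "mutant", "wildtype")
    histology = np.where(grade == "IV", "glioblastoma",
                         rng.choice(["astrocytoma", "oligodendroglioma"],
                                    size=n_samples))

    clinical = ClinicalTable(data=pd.DataFrame({
        "os_time": os_time, "os_status": os_status,
        "dfs_time": dfs_time, "dfs_status": dfs_status,
        "grade": grade, "idh_status": idh, "histology": histology,
    }, index=pd.Index(sample_ids, name="sample_id")), time_unit="months")

    return SyntheticCohort(
        expression=expression, gene_sets=gene_sets, mutations=mutations,
        copy_number_gene=copy_number_gene, copy_number_arm=copy_number_arm,
        clinical=clinical,
        strata=pd.Series(strata, index=pd.Index(sample_ids, name="sample_id"),
                         name="stratum"),
        immune_set_names=immune_names, pdl1_gene=pdl1_gene,
        planted_mutation_genes=planted, spec=spec)


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> dict[str, Path]:
    """Write every cohort table in the exact formats the readers accept."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "gene_sets": outdir / "gene_sets.gmt",
        "mutations": outdir / "mutations.maf",
        "copy_number_gene": outdir / "copy_number_genes.tsv",
        "copy_number_arm": outdir / "copy_number_arms.tsv",
        "clinical": outdir / "clinical.tsv",
        "strata": outdir / "ground_truth_strata.tsv",
    }
    cohort.expression.to_tsv(paths["expression"])
    cohort.gene_sets.to_gmt(paths["gene_sets"])
    cohort.mutations.to_maf(paths["mutations"])
    cohort.copy_number_gene.to_tsv(paths["copy_number_gene"])
    cohort.copy_number_arm.to_tsv(paths["copy_number_arm"])
    cohort.clinical.to_tsv(paths["clinical"])
    cohort.strata.to_csv(paths["strata"], sep="\t")
    (outdir / "spec.json").write_text(
        pd.Series(asdict(cohort.spec)).to_json(indent=1) + "\n")
    return paths
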