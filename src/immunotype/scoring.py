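"""Per-sample gene-set enrichment scoring.

Three statistics live here:

* :func:`ssgsea_score` — single-sample GSEA (ssGSEA). For one sample, genes are
  walked in decreasing-expression order and the score is the summed difference
  between two empirical distribution functions: the in-set CDF weighted by
  rank**alpha (largest expression = rank N, weights normalized to sum to 1) and
  the uniform out-of-set CDF. It measures how coordinately a gene set is up- or
  down-regulated within that single sample; being rank-based it is invariant to
  any strictly monotone transform of the sample's expression vector.
* :func:`estimate_scores` — signature-based immune and stromal content and the
  derived tumor purity, ``purity = cos(0.6049872018 + 0.0001467884 * score)``
  where ``score`` is the immune + stromal sum.
* :func:`signature_ratio` — the log2 ratio of mean linear-scale expression of
  two marker-gene signatures (e.g. CD8+ T cells vs regulatory T cells, or
  M1 vs M2 macrophages), a per-sample balance of immune-promoting versus
  immune-inhibiting activity.
"""

from __future__ import annotations

import importlib.resources
import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io_formats import ExpressionMatrix, GeneSetCollection, read_gmt

__all__ = [
    "EnrichmentMatrix",
    "ImmunePurityScores",
    "ssgsea_score",
    "estimate_scores",
    "signature_ratio",
    "load_estimate_signatures",
]

# Purity-from-score constants of the ESTIMATE method.
PURITY_INTERCEPT = 0.6049872018
PURITY_SLOPE = 0.0001467884


@dataclass
class EnrichmentMatrix:
    """Gene-set x sample enrichment scores.

    ``normalization`` is ``"raw"`` or ``"range"``; range-normalized scores are
    rescaled to [0, 1] by the global min/max over the whole collection.
    ``missing_sets`` lists sets with zero gene overlap (scores NaN).
    """

    scores: pd.DataFrame
    normalization: str = "raw"
    missing_sets: list[str] = field(default_factory=list)
    alpha: float = 0.25

    @property
    def set_names(self) -> list[str]:
        return self.scores.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.scores.columns.tolist()

    def to_tsv(self, path) -> None:
        from .io_formats import _write_sidecar
        self.scores.to_csv(path, sep="\t", index_label="gene_set")
        _write_sidecar(path, kind="enrichment", normalization=self.normalization,
                       alpha=self.alpha)


@dataclass
class ImmunePurityScores:
    """Per-sample immune/stromal scores and derived tumor purity.

    ``estimate_score = immune_score + stromal_score`` exactly; ``purity_raw``
    is the cosine formula value in [-1, 1] and ``purity`` its clip to [0, 1].
    """

    table: pd.DataFrame  # columns: immune_score, stromal_score, estimate_score, purity_raw, purity

    def __post_init__(self) -> None:
        t = self.table
        np.testing.assert_allclose(
            t["estimate_score"], t["immune_score"] + t["stromal_score"], rtol=0, atol=1e-9)

    @property
    def immune_score(self) -> pd.Series:
        return self.table["immune_score"]

    @property
    def purity(self) -> pd.Series:
        return self.table["purity"]


def _ssgsea_core(values: np.ndarray, masks: np.ndarray, alpha: float) -> np.ndarray:
    """Raw ssGSEA scores for every (set, sample) pair.

    values: genes x samples; masks: sets x genes boolean. Walk order is by
    decreasing expression with ties broken by input gene order (stable sort);
    rank weights use average ranks on ties so tied genes weigh equally.
    """
    n_genes, n_samples = values.shape
    # average ranks, largest expression -> rank N
    ranks = np.apply_along_axis(rankdata, 0, values)
    weights = np.abs(ranks) ** alpha
    order = np.argsort(-values, axis=0, kind="stable")
    w_ord = np.take_along_axis(weights, order, axis=0)

    out = np.empty((masks.shape[0], n_samples))
    for i, mask in enumerate(masks):
        n_out = n_genes - int(mask.sum())
        m_ord = mask[order]  # genes x samples boolean, set membership in walk order
        in_w = np.where(m_ord, w_ord, 0.0)
        in_cdf = np.cumsum(in_w, axis=0) / in_w.sum(axis=0)
        out_cdf = np.cumsum(~m_ord, axis=0) / n_out
        out[i] = (in_cdf - out_cdf).sum(axis=0)
    return out


def ssgsea_score(expr: ExpressionMatrix, sets: GeneSetCollection,
                 alpha: float = 0.25, normalize: bool = True) -> EnrichmentMatrix:
    """Score every gene set in every sample by the ssGSEA running sum.

    Parameters
    ----------
    expr
        Expression matrix (log scale assumed; only within-sample ranks are used).
    sets
        Gene sets; symbols absent from ``expr`` are dropped per set. A set with
        no overlap gets NaN scores and a warning; a set covering *all* genes is
        an error (the out-of-set distribution is undefined).
    alpha
        Rank-weighting exponent (>= 0). ``alpha=0`` gives the unweighted
        Kolmogorov running sum.
    normalize
        Rescale scores to [0, 1] by the global (max - min) over the whole
        collection; ``False`` returns raw running-sum totals.
    """
    if alpha < 0:
        raise ValueError(f"alpha must be >= 0, got {alpha}")
    gene_index = {g: i for i, g in enumerate(expr.gene_ids)}
    n_genes = len(gene_index)

    names = sets.names()
    masks = np.zeros((len(names), n_genes), dtype=bool)
    missing: list[str] = []
    for i, name in enumerate(names):
        idx = [gene_index[g] for g in sets[name] if g in gene_index]
        if not idx:
            missing.append(name)
            continue
        if len(idx) == n_genes:
            raise ValueError(
                f"gene set '{name}' covers every gene in the matrix; "
                "out-of-set distribution undefined")
        masks[i, idx] = True

    if missing:
        warnings.warn(f"gene sets with no overlapping genes (scores set NaN): {missing}")

    keep = [i for i, name in enumerate(names) if name not in missing]
    raw = np.full((len(names), expr.shape[1]), np.nan)
    if keep:
        raw[keep] = _ssgsea_core(expr.values.to_numpy(float), masks[keep], alpha)

    scores = pd.DataFrame(raw, index=names, columns=expr.sample_ids)
    normalization = "raw"
    if normalize:
        finite = scores.to_numpy()[np.isfinite(scores.to_numpy())]
        if finite.size:
            lo, hi = finite.min(), finite.max()
            if hi > lo:
                scores = (scores - lo) / (hi - lo)
            else:
                warnings.warn("degenerate score range (max == min); normalized scores set to 0")
                scores = scores * 0.0
        normalization = "range"
    return EnrichmentMatrix(scores=scores, normalization=normalization,
                            missing_sets=missing, alpha=alpha)


def load_estimate_signatures() -> tuple[GeneSetCollection, float]:
    """Load the packaged immune/stromal signatures and score scaling constant.

    The shipped signatures are a synthetic stand-in built from canonical
    immune and stromal marker genes (see ``_data/estimate_signatures_synthetic.gmt``),
    not the published 141-gene lists; pass your own collections to
    :func:`estimate_scores` to use different signatures.
    """
    data = importlib.resources.files("immunotype") / "_data"
    sig = read_gmt(str(data / "estimate_signatures_synthetic.gmt"))
    constants = json.loads((data / "estimate_constants.json").read_text())
    return sig, float(constants["score_scale"])


def estimate_scores(expr: ExpressionMatrix,
                    immune_sig: Sequence[str] | None = None,
                    stromal_sig: Sequence[str] | None = None,
                    score_scale: float | None = None) -> ImmunePurityScores:
    """Immune score, stromal score, and tumor purity per sample.

    Immune and stromal scores are raw ssGSEA scores of the two signatures
    multiplied by ``score_scale``; ``purity = cos(a + b * (immune + stromal))``
    with the ESTIMATE constants, monotonically decreasing in the combined
    score over the formula's working range, reported clipped to [0, 1].
    """
    if immune_sig is None or stromal_sig is None:
        packaged, packaged_scale = load_estimate_signatures()
        immune_sig = immune_sig or packaged["immune_signature"]
        stromal_sig = stromal_sig or packaged["stromal_signature"]
        if score_scale is None:
            score_scale = packaged_scale
    if score_scale is None:
        score_scale = 1.0

    sig = GeneSetCollection(sets={"immune_signature": list(immune_sig),
                                  "stromal_signature": list(stromal_sig)})
    present = set(expr.gene_ids)
    for name, genes in sig.sets.items():
        if not present.intersection(genes):
            raise ValueError(f"{name} has no genes in the expression matrix")

    enr = ssgsea_score(expr, sig, normalize=False)
    immune = enr.scores.loc["immune_signature"] * score_scale
    stromal = enr.scores.loc["stromal_signature"] * score_scale
    combined = immune + stromal
    purity_raw = np.cos(PURITY_INTERCEPT + PURITY_SLOPE * combined)
    table = pd.DataFrame({
        "immune_score": immune,
        "stromal_score": stromal,
        "estimate_score": combined,
        "purity_raw": purity_raw,
        "purity": purity_raw.clip(0.0, 1.0),
    })
    table.index.name = "sample_id"
    return ImmunePurityScores(table=table)


def signature_ratio(expr: ExpressionMatrix, sig_a: Sequence[str],
                    sig_b: Sequence[str]) -> pd.Series:
    """Per-sample log2 ratio of mean linear expression of two signatures.

    ``ratio = log2(mean expr over sig_a) - log2(mean expr over sig_b)``, means
    taken on linear scale (a log2 matrix is exponentiated first). Antisymmetric
    under swapping the signatures.
    """
    present = set(expr.gene_ids)
    genes_a = [g for g in sig_a if g in present]
    genes_b = [g for g in sig_b if g in present]
    if not genes_a or not genes_b:
        raise ValueError("both signatures need at least one gene in the matrix")
    linear = expr.linear_values()
    mean_a = linear.loc[genes_a].mean(axis=0)
    mean_b = linear.loc[genes_b].mean(axis=0)
    if (mean_a <= 0).any() or (mean_b <= 0).any():
        raise ValueError(
            "non-positive signature mean; supply linear-scale expression "
            "(or a correctly declared log2 matrix)")
    ratio = np.log2(mean_a) - np.log2(mean_b)
    ratio.name = "log2_signature_ratio"
    return ratio
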