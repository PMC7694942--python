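"""End-to-end convenience: expression -> enrichment -> subtype labels.

One call chains the per-cohort steps that every analysis repeats: ssGSEA
scoring of the 28 immune-cell signatures, per-feature Z-clip normalization,
and the three-cluster hierarchical cut with ordered labels. Each step remains
individually available in :mod:`immunotype.scoring` / :mod:`immunotype.subtyping`.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io_formats import ExpressionMatrix, GeneSetCollection
from .scoring import EnrichmentMatrix, ssgsea_score
from .subtyping import (NormalizedFeatureMatrix, SubtypeAssignment,
                        cluster_subtypes, zclip_normalize)

__all__ = ["SubtypingRun", "immune_subtypes"]


@dataclass
class SubtypingRun:
    """Everything one cohort's subtyping produced."""

    enrichment: EnrichmentMatrix
    features: NormalizedFeatureMatrix
    assignment: SubtypeAssignment


def immune_subtypes(expr: ExpressionMatrix, sets: GeneSetCollection,
                    immune_set_names: list[str] | None = None,
                    alpha: float = 0.25, k: int = 3,
                    method: str = "ward") -> SubtypingRun:
    """Score, normalize and cluster one cohort into ordered immunity subtypes.

    ``immune_set_names`` restricts clustering to the immune-cell signatures
    (all sets in the collection by default). Scoring, Z-clipping and the
    dendrogram cut use the package defaults unless overridden.
    """
    if immune_set_names is not None:
        sets = sets.subset(immune_set_names)
    enrichment = ssgsea_score(expr, sets, alpha=alpha, normalize=True)
    features = zclip_normalize(enrichment)
    assignment = cluster_subtypes(features, k=k, method=method)
    return SubtypingRun(enrichment=enrichment, features=features,
                        assignment=assignment)
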