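"""Sample subtyping on immune-cell enrichment profiles.

Samples are hierarchically clustered (Ward linkage on Euclidean distance by
default) on their Z-scored, clipped enrichment profiles over the 28 immune-cell
signatures and the dendrogram is cut into three clusters. Clusters are then
labeled ``immunity-high`` / ``immunity-medium`` / ``immunity-low`` by
descending mean feature Z — the same ordering the immune score reproduces on
every cohort where the clustering is meaningful.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import pdist

from .scoring import EnrichmentMatrix

__all__ = [
    "SUBTYPE_LABELS",
    "NormalizedFeatureMatrix",
    "SubtypeAssignment",
    "zclip_normalize",
    "cluster_subtypes",
    "tertile_split",
]

SUBTYPE_LABELS = ("immunity-high", "immunity-medium", "immunity-low")
Z_CLIP = 3.0


@dataclass
class NormalizedFeatureMatrix:
    """Features x samples matrix, Z-scored per feature and clipped to [-3, 3]."""

    z: pd.DataFrame
    dropped_features: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        vals = self.z.to_numpy()
        if vals.size and (np.abs(vals) > Z_CLIP + 1e-12).any():
            raise ValueError("normalized features exceed the [-3, 3] clip range")

    @property
    def feature_names(self) -> list[str]:
        return self.z.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.z.columns.tolist()


@dataclass
class SubtypeAssignment:
    """Per-sample subtype labels with cluster provenance.

    ``labels`` maps sample id -> one of :data:`SUBTYPE_LABELS`;
    ``cluster_index`` holds the raw dendrogram-cut cluster id and
    ``ordering_key`` the per-cluster mean feature Z used to order the labels
    (strictly decreasing high -> medium -> low).
    """

    labels: pd.Series
    cluster_index: pd.Series
    ordering_key: dict[int, float]
    linkage: str = "ward"

    def samples(self, label: str) -> list[str]:
        return self.labels.index[self.labels == label].tolist()

    def to_tsv(self, path) -> None:
        from .io_formats import _write_sidecar
        out = pd.DataFrame({
            "label": self.labels,
            "cluster_index": self.cluster_index,
            "ordering_key": self.cluster_index.map(self.ordering_key),
        })
        out.to_csv(path, sep="\t", index_label="sample_id")
        _write_sidecar(path, kind="subtypes", linkage=self.linkage)


def zclip_normalize(scores: EnrichmentMatrix | pd.DataFrame) -> NormalizedFeatureMatrix:
    """Z-score each feature across samples (sample sd, n-1) and clip to [-3, 3].

    Zero-variance features are dropped with a warning; a single-sample input is
    an error (Z undefined).
    """
    table = scores.scores if isinstance(scores, EnrichmentMatrix) else scores
    if table.shape[1] < 2:
        raise ValueError("Z normalization needs at least 2 samples")
    sd = table.std(axis=1, ddof=1)
    constant = sd[(sd == 0) | sd.isna()].index.tolist()
    if constant:
        warnings.warn(f"dropping zero-variance feature(s): {constant}")
        table = table.drop(index=constant)
        sd = sd.drop(index=constant)
    z = table.sub(table.mean(axis=1), axis=0).div(sd, axis=0)
    return NormalizedFeatureMatrix(z=z.clip(-Z_CLIP, Z_CLIP), dropped_features=constant)


def cluster_subtypes(features: NormalizedFeatureMatrix, k: int = 3,
                     method: str = "ward", metric: str = "euclidean") -> SubtypeAssignment:
    """Cut a hierarchical clustering of sample profiles into ``k`` ordered subtypes.

    Clusters are labeled by descending mean feature Z: the cluster with the
    highest mean becomes ``immunity-high``, the lowest ``immunity-low``. With
    ``k != 3`` the labels are ``immunity-1`` (highest) .. ``immunity-k``.
    """
    n = len(features.sample_ids)
    if n < k:
        raise ValueError(f"cannot cut {n} samples into {k} clusters")
    profiles = features.z.to_numpy(float).T  # samples x features
    Z = scipy_linkage(pdist(profiles, metric=metric), method=method)
    raw = fcluster(Z, t=k, criterion="maxclust")
    found = np.unique(raw)
    assert len(found) == k, f"dendrogram cut produced {len(found)} clusters, expected {k}"

    mean_z = {int(c): float(profiles[raw == c].mean()) for c in found}
    # descending mean Z; ties broken by cluster id for determinism
    ordered = sorted(mean_z, key=lambda c: (-mean_z[c], c))
    if k == 3:
        label_names = list(SUBTYPE_LABELS)
    else:
        label_names = [f"immunity-{i + 1}" for i in range(k)]
    label_of = {c: label_names[i] for i, c in enumerate(ordered)}

    index = pd.Index(features.sample_ids, name="sample_id")
    labels = pd.Series([label_of[c] for c in raw], index=index, name="label")
    cluster_index = pd.Series(raw.astype(int), index=index, name="cluster_index")
    return SubtypeAssignment(labels=labels, cluster_index=cluster_index,
                             ordering_key=mean_z, linkage=method)


def tertile_split(scores: pd.Series) -> pd.Series:
    """Split samples into high/middle/low thirds of a per-sample score.

    The top ceil(n/3) samples are ``high-third`` and the bottom ceil(n/3)
    ``low-third``; the remainder is ``middle``. Ties at the boundaries are
    resolved by stable rank order (input order), with a warning when a
    boundary falls inside a tie run.
    """
    n = len(scores)
    if n < 3:
        raise ValueError("tertile split needs at least 3 samples")
    m = int(np.ceil(n / 3))
    order = np.argsort(scores.to_numpy(), kind="stable")  # ascending, stable
    vals = scores.to_numpy()[order]
    for cut in (m - 1, n - m - 1):
        if 0 <= cut < n - 1 and vals[cut] == vals[cut + 1]:
            warnings.warn("tied scores at a tertile boundary; split by stable input order")
            break
    out = np.array(["middle"] * n, dtype=object)
    out[order[:m]] = "low-third"
    out[order[n - m:]] = "high-third"
    return pd.Series(out, index=scores.index, name="tertile")
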