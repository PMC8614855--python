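"""Expression-pattern clustering of DELs and pathway over-representation.

DEL stage profiles (replicate-mean TPM, row z-scored) are partitioned by
k-means into k=8 temporal archetypes; each cluster's cis-target genes are
tested for pathway over-representation with the upper-tail hypergeometric
test at raw p < 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .model import ExpressionMatrix, ValidationError

logger = logging.getLogger(__name__)

N_CLUSTERS = 8
ENRICH_ALPHA = 0.05


def stage_means(expr: ExpressionMatrix, feature_ids=None) -> pd.DataFrame:
    """Arithmetic mean expression per stage (features x stages, stage order
    preserved)."""
    values = expr.stage_means()
    if feature_ids is not None:
        values = values.loc[[f for f in feature_ids if f in values.index]]
    return values


def zscore_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-row standardization to mean 0, population SD 1.

    Zero-variance rows carry no pattern information for clustering and are
    dropped with a warning.
    """
    arr = matrix.to_numpy(dtype=float)
    sd = arr.std(axis=1, ddof=0)
    keep = sd > 0
    dropped = matrix.index[~keep]
    if len(dropped):
        logger.warning("dropping %d zero-variance rows before clustering", len(dropped))
    arr = arr[keep]
    z = (arr - arr.mean(axis=1, keepdims=True)) / sd[keep, None]
    return pd.DataFrame(z, index=matrix.index[keep], columns=matrix.columns)


@dataclass
class ClusterAssignment:
    """K-means result with canonical labels 1..k."""

    labels: pd.Series  # feature_id -> cluster label (1..k)
    centroids: pd.DataFrame  # k rows x stage columns, index = label
    inertia: float  # within-cluster sum of squares

    @property
    def k(self) -> int:
        return len(self.centroids)

    def members(self, label: int) -> list[str]:
        return list(self.labels.index[self.labels == label])

    def sizes(self) -> dict[int, int]:
        return {int(l): int((self.labels == l).sum()) for l in self.centroids.index}


def kmeans_cluster(
    matrix: pd.DataFrame,
    k: int = N_CLUSTERS,
    seed: int = 0,
    n_init: int = 25,
    max_iter: int = 300,
) -> ClusterAssignment:
    """Lloyd's k-means with k-means++ seeding, best of ``n_init`` restarts.

    Deterministic given ``seed``. Labels are renumbered canonically (1..k in
    order of first appearance along the row order) so runs are comparable.
    """
    if len(matrix) < k:
        raise ValidationError(f"need >= {k} rows to form {k} clusters, got {len(matrix)}")
    km = KMeans(
        n_clusters=k, n_init=n_init, max_iter=max_iter, random_state=seed
    ).fit(matrix.to_numpy(dtype=float))
    raw = km.labels_
    # canonical relabeling: cluster of the first row becomes 1, etc.
    order: dict[int, int] = {}
    for lab in raw:
        if lab not in order:
            order[lab] = len(order) + 1
    labels = pd.Series([order[l] for l in raw], index=matrix.index, name="cluster")
    centroid_rows = sorted(order, key=order.get)
    centroids = pd.DataFrame(
        km.cluster_centers_[centroid_rows],
        index=[order[l] for l in centroid_rows],
        columns=matrix.columns,
    )
    return ClusterAssignment(labels=labels, centroids=centroids, inertia=float(km.inertia_))


@dataclass(frozen=True)
class EnrichmentResult:
    pathway_id: str
    pathway_size: int  # |pathway ∩ universe|
    overlap: int
    p: float
    significant: bool


def hypergeom_enrich(
    query: set[str],
    pathways: Mapping[str, set[str]],
    universe: set[str],
    alpha: float = ENRICH_ALPHA,
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric over-representation test per pathway.

    p = P(X >= overlap) drawing |query| genes from a universe of
    |universe| containing |pathway ∩ universe| successes. Pathways are
    intersected with the universe; results sorted by p then pathway id.
    """
    if not universe:
        raise ValidationError("empty gene universe")
    if not query:
        raise ValidationError("empty query gene set")
    if not query <= universe:
        raise ValidationError("query must be a subset of the universe")
    results = []
    M, n = len(universe), len(query)
    for pid in sorted(pathways):
        members = pathways[pid] & universe
        if not members:
            continue
        K = len(members)
        overlap = len(query & members)
        p = float(stats.hypergeom.sf(overlap - 1, M, K, n))
        p = min(p, 1.0)
        results.append(
            EnrichmentResult(
                pathway_id=pid,
                pathway_size=K,
                overlap=overlap,
                p=p,
                significant=p < alpha,
            )
        )
    results.sort(key=lambda r: (r.p, r.pathway_id))
    return results
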