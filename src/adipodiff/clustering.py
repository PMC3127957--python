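"""k-means clustering of combined expression profiles, validated by PCA.

Profiles from the two cell models are joined on EST id into concatenated
log2-ratio vectors, grouped into k clusters (k = 6 in the reference
workflow) by Euclidean k-means with multiple restarts, and the separation
is inspected in the space of the first three principal components.
Cluster labels are exported as letters A, B, C, ...
"""

from __future__ import annotations

import logging
import string
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

__all__ = [
    "ClusterModel",
    "combine_profiles",
    "kmeans_cluster",
    "pca_project",
    "cluster_centroid_view",
    "cluster_letters",
]

logger = logging.getLogger(__name__)


def combine_profiles(profiles_a: pd.DataFrame, profiles_b: pd.DataFrame) -> pd.DataFrame:
    """Inner-join two wide profile matrices (rows ESTs, columns time points).

    The result concatenates model-A columns then model-B columns; ESTs
    present in only one model are dropped (count logged).  Rows with any
    missing value are removed so the clustering input is complete.
    """
    common = profiles_a.index.intersection(profiles_b.index)
    if len(common) == 0:
        raise ValueError("no EST ids shared between the two profile sets")
    dropped = (len(profiles_a) - len(common)) + (len(profiles_b) - len(common))
    if dropped:
        logger.info("combine_profiles: dropped %d ESTs missing in one model", dropped)
    a = profiles_a.loc[common].add_prefix("A_")
    b = profiles_b.loc[common].add_prefix("B_")
    combined = pd.concat([a, b], axis=1).dropna()
    if combined.empty:
        raise ValueError("no complete combined profiles after joining")
    return combined


@dataclass
class ClusterModel:
    """Fitted k-means partition of combined profiles."""

    k: int
    centroids: np.ndarray
    assignments: pd.Series  # est_id -> 0-based label
    inertia: float  # within-cluster sum of squares

    def letters(self) -> pd.Series:
        """Assignments as letters A..; cluster 0 -> 'A'."""
        return self.assignments.map(lambda i: cluster_letters(self.k)[i])


def cluster_letters(k: int) -> list[str]:
    return list(string.ascii_uppercase[:k])


def kmeans_cluster(matrix: pd.DataFrame, k: int = 6, seed: int = 0,
                   n_restarts: int = 20, standardize: bool = False) -> ClusterModel:
    """Euclidean k-means, best of ``n_restarts`` k-means++ initialisations.

    Log2-ratio profiles are clustered unscaled by default (the profiles
    are already on a common log-ratio scale); ``standardize`` switches on
    per-column standardisation.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(matrix) < k:
        raise ValueError(f"cannot form {k} clusters from {len(matrix)} profiles")
    X = matrix.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("clustering input contains missing values")
    if standardize:
        sd = X.std(axis=0, ddof=0)
        X = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_restarts,
                random_state=seed).fit(X)
    return ClusterModel(k=k, centroids=km.cluster_centers_,
                        assignments=pd.Series(km.labels_, index=matrix.index,
                                              name="cluster"),
                        inertia=float(km.inertia_))


def pca_project(matrix: pd.DataFrame, n_components: int = 3,
                labels: pd.Series | None = None) -> tuple[pd.DataFrame, np.ndarray]:
    """Column-centred PCA scores and explained-variance ratios.

    Components are ordered by decreasing explained variance; when cluster
    ``labels`` are given they are attached for colour-coded plotting.
    """
    if len(matrix) < 2:
        raise ValueError("PCA needs at least 2 profiles")
    X = matrix.to_numpy(dtype=float)
    if np.allclose(X.var(axis=0), 0):
        raise ValueError("constant matrix has no principal components")
    n_components = min(n_components, min(X.shape))
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(X - X.mean(axis=0))
    out = pd.DataFrame(scores, index=matrix.index,
                       columns=[f"PC{i + 1}" for i in range(n_components)])
    if labels is not None:
        out["cluster"] = labels.reindex(out.index)
    return out, pca.explained_variance_ratio_


def cluster_centroid_view(model: ClusterModel, matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-cluster mean +/- SD of each time point (for centroid line plots)."""
    labels = model.assignments.reindex(matrix.index)
    rows = []
    for cluster, grp in matrix.groupby(labels):
        for col in matrix.columns:
            rows.append((cluster_letters(model.k)[int(cluster)], col,
                         float(grp[col].mean()),
                         float(grp[col].std(ddof=0)),
                         len(grp)))
    return pd.DataFrame(rows, columns=["cluster", "time", "mean", "sd", "n"])
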