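"""Bootstrap HDBSCAN clustering of pooled embeddings with silhouette scoring.

Each bootstrap iteration samples a fixed number of orthologous groups
without replacement, takes all of their member sequences, clusters the
pooled embeddings with HDBSCAN, and scores the partition with the
silhouette coefficient S(i) = (b(i) - a(i)) / max(a(i), b(i)) averaged
over non-noise points.  The maximum over iterations is the "best-case"
summary.  Iterations that yield fewer than two clusters have no defined
silhouette and are recorded as skipped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import HDBSCAN

from .data import OrthologGroupSet

NOISE = -1


@dataclass(frozen=True)
class BootstrapConfig:
    iterations: int = 1000
    groups_per_iteration: int = 500
    seed: int = 0


@dataclass(frozen=True)
class DensityClusterParams:
    min_cluster_size: int = 10
    min_samples: int = 5
    selection_epsilon: float = 1.0
    alpha: float = 1.0

    def __post_init__(self):
        if self.min_cluster_size < 2:
            raise ValueError("min_cluster_size must be at least 2")


@dataclass
class ClusteringReport:
    per_iteration_scores: list[float | None]
    skipped: list[tuple[int, str]]

    @property
    def defined_scores(self) -> list[float]:
        return [s for s in self.per_iteration_scores if s is not None]

    @property
    def max_score(self) -> float | None:
        defined = self.defined_scores
        return max(defined) if defined else None

    def summary(self) -> dict:
        defined = self.defined_scores
        return {
            "iterations": len(self.per_iteration_scores),
            "defined": len(defined),
            "max_score": self.max_score,
            "mean_score": float(np.mean(defined)) if defined else None,
            "skipped": [{"iteration": i, "reason": r} for i, r in self.skipped],
        }


def silhouette_score(points: np.ndarray, labels: np.ndarray) -> float | None:
    """Mean silhouette over non-noise points; None when < 2 clusters.

    a(i) is the mean Euclidean distance to the other members of i's
    cluster (points in singleton clusters score 0); b(i) is the smallest
    mean distance to any other cluster.
    """
    points = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    keep = labels != NOISE
    points, labels = points[keep], labels[keep]
    cluster_ids = np.unique(labels)
    if len(cluster_ids) < 2:
        return None
    dist = cdist(points, points)
    scores = np.zeros(len(points))
    members = {c: np.flatnonzero(labels == c) for c in cluster_ids}
    for i in range(len(points)):
        own = members[labels[i]]
        if len(own) == 1:
            scores[i] = 0.0
            continue
        a = dist[i, own].sum() / (len(own) - 1)
        b = min(dist[i, members[c]].mean() for c in cluster_ids if c != labels[i])
        denom = max(a, b)
        scores[i] = 0.0 if denom == 0.0 else (b - a) / denom
    return float(scores.mean())


def cluster_embeddings(points: np.ndarray, params: DensityClusterParams) -> np.ndarray:
    """HDBSCAN labels (−1 = noise) with the given parameters passed through."""
    points = np.asarray(points, dtype=float)
    if len(points) < params.min_cluster_size:
        raise ValueError(
            f"{len(points)} points is fewer than min_cluster_size "
            f"{params.min_cluster_size}"
        )
    kwargs = dict(
        min_cluster_size=params.min_cluster_size,
        min_samples=params.min_samples,
        cluster_selection_epsilon=params.selection_epsilon,
        alpha=params.alpha,
        copy=True,
    )
    try:
        return HDBSCAN(**kwargs).fit_predict(points)
    except TypeError:
        # scikit-learn's epsilon search raises TypeError when epsilon exceeds
        # every dendrogram merge distance; the correct answer there is the
        # single root cluster, which allow_single_cluster returns.
        return HDBSCAN(**kwargs, allow_single_cluster=True).fit_predict(points)
    except ValueError:
        # degenerate geometry (e.g. all points identical): treat as one cluster
        return np.zeros(len(points), dtype=int)


def bootstrap_cluster_silhouette(
    data: OrthologGroupSet,
    pooled: dict[str, np.ndarray],
    boot: BootstrapConfig,
    params: DensityClusterParams = DensityClusterParams(),
) -> ClusteringReport:
    group_ids = data.group_ids
    if boot.groups_per_iteration > len(group_ids):
        raise ValueError(
            f"cannot sample {boot.groups_per_iteration} groups from "
            f"{len(group_ids)} available"
        )
    scores: list[float | None] = []
    skipped: list[tuple[int, str]] = []
    for i in range(boot.iterations):
        rng = np.random.default_rng(boot.seed + i)
        chosen = rng.choice(len(group_ids), size=boot.groups_per_iteration, replace=False)
        ids = [sid for gi in sorted(chosen) for sid in data.members(group_ids[gi])]
        points = np.stack([pooled[sid] for sid in ids])
        labels = cluster_embeddings(points, params)
        score = silhouette_score(points, labels)
        scores.append(score)
        if score is None:
            skipped.append((i, "fewer than two clusters"))
    return ClusteringReport(scores, skipped)
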