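"""Spectral clustering of patient samples.

The M2 distance matrix is converted to a similarity (Gaussian kernel with
a median-heuristic bandwidth, since spectral clustering needs an affinity)
and clustered with the standard normalized-Laplacian spectral pipeline.
The "Expression" baseline clusters samples directly from their
metabolic-gene expression vectors through the same conversion, using
Euclidean distances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import SpectralClustering

from .model_io import ExpressionMatrix
from .network_distance import DistanceMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ClusteringResult",
    "distance_to_affinity",
    "cluster_samples",
    "cluster_distance_matrix",
    "cluster_expression_baseline",
]


@dataclass
class ClusteringResult:
    """Predicted cluster labels per sample, canonically relabeled so that
    cluster ids are numbered by first occurrence in sample order."""

    sample_ids: list[str]
    labels: np.ndarray
    n_clusters: int
    source: str  # "expression" | "whole_graph" | "summarized_graph"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape != (len(self.sample_ids),):
            raise ValueError("label vector length does not match samples")
        present = np.unique(self.labels)
        if not np.array_equal(present, np.arange(self.n_clusters)):
            raise ValueError(
                f"labels must cover 0..{self.n_clusters - 1} with no empty cluster"
            )

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("sample_id\tpredicted_label\n")
            for s, lab in zip(self.sample_ids, self.labels):
                fh.write(f"{s}\t{lab}\n")


def _canonical_relabel(labels: np.ndarray) -> np.ndarray:
    mapping: dict[int, int] = {}
    out = np.empty_like(labels)
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


def distance_to_affinity(D: DistanceMatrix | np.ndarray, sigma: float | str = "auto") -> np.ndarray:
    """Gaussian-kernel conversion A = exp(-D^2 / (2 sigma^2)).

    With ``sigma="auto"`` the bandwidth is the median off-diagonal
    distance; an all-zero distance matrix then has no defined bandwidth
    and an explicit sigma must be supplied.
    """
    Dm = D.D if isinstance(D, DistanceMatrix) else np.asarray(D, dtype=float)
    n = Dm.shape[0]
    if sigma == "auto":
        off = Dm[~np.eye(n, dtype=bool)]
        sigma_val = float(np.median(off)) if n > 1 else 0.0
        if sigma_val <= 0:
            raise ValueError(
                "median off-diagonal distance is 0; supply an explicit sigma"
            )
    else:
        sigma_val = float(sigma)
        if sigma_val <= 0:
            raise ValueError("sigma must be positive")
    A = np.exp(-(Dm**2) / (2.0 * sigma_val**2))
    np.fill_diagonal(A, 1.0)
    return (A + A.T) / 2.0


def cluster_samples(
    A: np.ndarray,
    sample_ids: Sequence[str],
    n_clusters: int,
    seed: int,
    source: str = "summarized_graph",
) -> ClusteringResult:
    """Spectral clustering on a precomputed affinity matrix (normalized
    graph Laplacian, top eigenvectors, seeded k-means), deterministic for
    fixed (A, n_clusters, seed)."""
    A = np.asarray(A, dtype=float)
    n = A.shape[0]
    if A.shape != (n, n) or not np.allclose(A, A.T):
        raise ValueError("affinity must be square and symmetric")
    if np.any(A < 0):
        raise ValueError("affinity must be non-negative")
    if not 2 <= n_clusters <= n:
        raise ValueError(f"n_clusters={n_clusters} must be in [2, {n}]")
    if n_clusters == n:
        labels = np.arange(n)
    else:
        sc = SpectralClustering(
            n_clusters=n_clusters,
            affinity="precomputed",
            assign_labels="kmeans",
            n_init=10,
            random_state=seed,
        )
        labels = sc.fit_predict(A)
    labels = _canonical_relabel(labels)
    return ClusteringResult(
        sample_ids=list(sample_ids),
        labels=labels,
        n_clusters=len(np.unique(labels)),
        source=source,
    )


def cluster_distance_matrix(
    D: DistanceMatrix,
    n_clusters: int,
    seed: int,
    sigma: float | str = "auto",
    source: str = "summarized_graph",
) -> ClusteringResult:
    """Convenience wrapper: distance -> Gaussian affinity -> spectral clustering."""
    A = distance_to_affinity(D, sigma=sigma)
    return cluster_samples(A, D.sample_ids, n_clusters, seed, source=source)


def cluster_expression_baseline(
    expr: ExpressionMatrix,
    gene_subset: Iterable[str],
    n_clusters: int,
    seed: int,
    sigma: float | str = "auto",
) -> ClusteringResult:
    """The "Expression" baseline: spectral clustering of samples from their
    metabolic-gene expression vectors (Euclidean distances, same Gaussian
    conversion and algorithm as the network route)."""
    subset = sorted(set(gene_subset) & set(expr.genes))
    if not subset:
        raise ValueError("gene subset does not intersect the expression matrix")
    logger.info("expression baseline uses %d metabolic genes", len(subset))
    idx = [expr.genes.index(g) for g in subset]
    X = expr.values[idx, :].T  # samples x genes
    Dm = squareform(pdist(X, metric="euclidean"))
    A = distance_to_affinity(Dm, sigma=sigma)
    return cluster_samples(A, expr.samples, n_clusters, seed, source="expression")
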