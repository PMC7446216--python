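"""Graph summarization: spectral partition of the shared topology and
supernode collapse ``W_s = Q^T W Q``.

The partition is computed once per dataset on the unweighted adjacency
structure common to all samples (all sample graphs share nodes and edges;
only the weights differ), using the unnormalized graph Laplacian
``L = D - A``: the eigenvectors of the k smallest eigenvalues form an
l x k feature matrix whose rows are clustered with seeded k-means. The
same partition is then applied to every sample's weight matrix, collapsing
each cluster into a supernode. Total edge weight is conserved exactly by
the quadratic form, and the diagonal of ``W_s`` (intra-supernode weight)
is retained: it participates in supernode strength and random-walk
self-transitions downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.linalg import eigh
from sklearn.cluster import KMeans

from .network_construction import SampleGraph, _component_labels

logger = logging.getLogger(__name__)

__all__ = [
    "NodePartition",
    "SummarizedGraph",
    "spectral_partition",
    "identity_partition",
    "summarize",
    "sweep_supernode_counts",
    "write_partition",
    "read_partition",
]

_KMEANS_RETRIES = 5


@dataclass
class NodePartition:
    """Assignment of l nodes to k clusters (one cluster per node)."""

    k: int
    labels: np.ndarray  # shape (l,), values in 0..k-1
    node_order: tuple[str, ...]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape != (len(self.node_order),):
            raise ValueError("label vector length does not match node order")
        if self.labels.min(initial=0) < 0 or (
            len(self.labels) and self.labels.max() >= self.k
        ):
            raise ValueError("labels out of range 0..k-1")
        counts = np.bincount(self.labels, minlength=self.k)
        if np.any(counts == 0):
            raise ValueError(f"empty clusters: {np.flatnonzero(counts == 0).tolist()}")

    @property
    def l(self) -> int:  # noqa: E743 - field name from the indicator-matrix notation
        return len(self.node_order)

    @property
    def Q(self) -> np.ndarray:
        """l x k binary indicator matrix with exactly one 1 per row."""
        Q = np.zeros((self.l, self.k))
        Q[np.arange(self.l), self.labels] = 1.0
        return Q

    def same_partition(self, other: "NodePartition") -> bool:
        return (
            self.k == other.k
            and self.node_order == other.node_order
            and np.array_equal(self.labels, other.labels)
        )


@dataclass
class SummarizedGraph:
    """k x k supernode weight matrix plus the partition that produced it."""

    sample_id: str
    k: int
    W_s: np.ndarray
    partition: NodePartition

    def __post_init__(self) -> None:
        self.W_s = np.asarray(self.W_s, dtype=float)
        if self.W_s.shape != (self.k, self.k):
            raise ValueError("W_s shape does not match k")
        if not np.allclose(self.W_s, self.W_s.T):
            raise ValueError("W_s must be symmetric")

    @property
    def total_weight(self) -> float:
        return float(self.W_s.sum())


def laplacian(adjacency: np.ndarray) -> np.ndarray:
    """Unnormalized graph Laplacian L = D - A."""
    A = np.asarray(adjacency, dtype=float)
    return np.diag(A.sum(axis=1)) - A


def spectral_partition(
    adjacency: np.ndarray,
    k: int,
    seed: int,
    node_order: Sequence[str] | None = None,
) -> NodePartition:
    """Partition a connected unweighted graph into k clusters by spectral
    clustering on ``L = D - A``.

    The k eigenvectors of the smallest Laplacian eigenvalues are used,
    unnormalized, as node features for k-means (10 restarts, seeded).
    Deterministic given (adjacency, k, seed).
    """
    A = np.asarray(adjacency, dtype=float)
    l = A.shape[0]
    if A.shape != (l, l) or not np.allclose(A, A.T):
        raise ValueError("adjacency must be square and symmetric")
    if node_order is None:
        node_order = tuple(f"n{i}" for i in range(l))
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > l:
        raise ValueError(f"k={k} exceeds the number of nodes l={l}")
    if k == l:
        # forced by the no-empty-cluster invariant: every node its own supernode
        return identity_partition(node_order)
    n_comp, _ = _component_labels(A > 0)
    if n_comp != 1:
        raise ValueError(
            f"graph must be connected (found {n_comp} components); "
            "apply largest_connected_component first"
        )
    L = laplacian(A)
    eigvals, eigvecs = eigh(L, subset_by_index=[0, k - 1])
    n_zero = int(np.sum(np.abs(eigvals) < 1e-8))
    if n_zero != 1:
        logger.warning(
            "Laplacian has %d near-zero eigenvalues; expected exactly 1 for a "
            "connected graph",
            n_zero,
        )
    for attempt in range(_KMEANS_RETRIES):
        km = KMeans(n_clusters=k, n_init=10, random_state=seed + attempt)
        labels = km.fit_predict(eigvecs)
        if len(np.unique(labels)) == k:
            if attempt:
                logger.info("k-means produced empty clusters; succeeded on retry %d", attempt)
            return NodePartition(k=k, labels=labels, node_order=tuple(node_order))
    raise RuntimeError(
        f"k-means left empty clusters after {_KMEANS_RETRIES} reinitializations"
    )


def identity_partition(node_order: Sequence[str]) -> NodePartition:
    """k = l partition mapping every node to its own supernode."""
    l = len(node_order)
    return NodePartition(k=l, labels=np.arange(l), node_order=tuple(node_order))


def summarize(g: SampleGraph, partition: NodePartition) -> SummarizedGraph:
    """Collapse a sample graph onto supernodes: ``W_s = Q^T W Q``."""
    if g.nodes != partition.node_order:
        diff = set(g.nodes).symmetric_difference(partition.node_order)
        raise ValueError(
            f"graph nodes and partition node order differ "
            f"(symmetric difference of size {len(diff)}: {sorted(diff)[:10]})"
        )
    Q = partition.Q
    W_s = Q.T @ g.W @ Q
    W_s = (W_s + W_s.T) / 2.0  # exact symmetrization against fp drift
    return SummarizedGraph(sample_id=g.sample_id, k=partition.k, W_s=W_s, partition=partition)


def sweep_supernode_counts(
    graphs: Sequence[SampleGraph],
    ks: Iterable[int],
    seed: int = 0,
) -> dict[int, list[SummarizedGraph]]:
    """Summarize every sample at each supernode count k.

    One shared partition per k (computed on the common unweighted structure
    with the same seed) is applied to all samples. Duplicate k values are
    deduplicated with a warning; k equal to the node count uses the
    identity partition.
    """
    if not graphs:
        raise ValueError("no graphs supplied")
    ks = list(ks)
    unique_ks = sorted(set(ks))
    if len(unique_ks) != len(ks):
        logger.warning("duplicate supernode counts removed from sweep: %s", ks)
    ref = graphs[0]
    for g in graphs[1:]:
        if g.nodes != ref.nodes or not np.array_equal(g.structure, ref.structure):
            raise ValueError(f"sample {g.sample_id} does not share the dataset topology")
    out: dict[int, list[SummarizedGraph]] = {}
    for k in unique_ks:
        part = spectral_partition(
            ref.structure.astype(float), k, seed=seed, node_order=ref.nodes
        )
        out[k] = [summarize(g, part) for g in graphs]
    return out


# ---------------------------------------------------------------------------
# persistence


def write_partition(partition: NodePartition, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("node_id\tcluster_id\n")
        for nid, lab in zip(partition.node_order, partition.labels):
            fh.write(f"{nid}\t{lab}\n")


def read_partition(path: str | Path) -> NodePartition:
    nodes: list[str] = []
    labels: list[int] = []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            nid, lab = line.rstrip("\n").split("\t")
            nodes.append(nid)
            labels.append(int(lab))
    return NodePartition(
        k=max(labels) + 1, labels=np.asarray(labels), node_order=tuple(nodes)
    )
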