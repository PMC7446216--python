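"""The M-squared network distance between summarized sample networks.

Each summarized network is turned into a random-walk transition matrix:
the supernode weight matrix rescaled by node strength, so that each column
is the one-step destination distribution of a walker located at that
supernode. The distance between two networks sharing a partition is the
average, over the k supernodes, of the Jensen-Shannon distance between the
corresponding one-step distributions:

    M2(Gp, Gq) = (1/k) * sum_i d_JS(T^p_i, T^q_i)

with d_JS the square root of the Jensen-Shannon divergence in base-2
logarithms, so every term — and hence M2 — lies in [0, 1]. Because the
weight matrices are symmetric, the distribution of supernode i equals row i
of W_s renormalized by strength(i); the row/column convention is therefore
immaterial here and is fixed to rows for implementation clarity.

d_JS is a metric and an average of metrics over coordinates is again a
metric, so M2 is symmetric, satisfies the triangle inequality, and is zero
exactly on identical transition structures. Transition matrices are
invariant under global rescaling of W, so M2 compares weight *profiles*,
not absolute expression scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import rel_entr

from .summarization import NodePartition, SummarizedGraph

logger = logging.getLogger(__name__)

__all__ = [
    "TransitionMatrix",
    "DistanceMatrix",
    "transition_matrix",
    "node_distributions",
    "js_divergence",
    "js_distance",
    "m2_distance",
    "pairwise_distances",
]

_LN2 = np.log(2.0)


@dataclass
class TransitionMatrix:
    """Column-stochastic one-step random-walk matrix of a summarized network.

    ``T[i, j]`` is the probability that a walker at supernode j steps to
    supernode i. Columns of zero strength use the absorbing convention
    (self-probability 1).
    """

    sample_id: str
    k: int
    T: np.ndarray
    partition: NodePartition | None = None

    def __post_init__(self) -> None:
        self.T = np.asarray(self.T, dtype=float)
        if self.T.shape != (self.k, self.k):
            raise ValueError("T shape does not match k")
        colsums = self.T.sum(axis=0)
        if np.any(np.abs(colsums - 1.0) > 1e-9):
            raise ValueError("every column of T must sum to 1")

    def distributions(self) -> np.ndarray:
        """Row-stacked per-supernode distributions (row i = distribution of
        supernode i = column i of T)."""
        return self.T.T.copy()


@dataclass
class DistanceMatrix:
    """Symmetric n x n matrix of pairwise M2 distances between samples."""

    sample_ids: list[str]
    D: np.ndarray

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        n = len(self.sample_ids)
        if self.D.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.D, self.D.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.abs(np.diag(self.D)) > 1e-12):
            raise ValueError("distance matrix diagonal must be zero")
        if self.D.min() < -1e-12 or self.D.max() > 1 + 1e-12:
            raise ValueError("M2 distances must lie in [0, 1]")

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.D, index=self.sample_ids, columns=self.sample_ids).to_csv(
            path, sep="\t", index_label="sample"
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(sample_ids=[str(s) for s in df.columns], D=df.to_numpy(dtype=float))


def _strength_distributions(W_s: np.ndarray) -> np.ndarray:
    """Per-supernode one-step distributions: row i = W_s[i, :]/strength(i),
    with the absorbing convention for zero-strength supernodes."""
    if np.any(W_s < 0):
        raise ValueError("negative supernode weight")
    strength = W_s.sum(axis=1)
    P = np.zeros_like(W_s, dtype=float)
    pos = strength > 0
    P[pos] = W_s[pos] / strength[pos, None]
    zero = np.flatnonzero(~pos)
    if zero.size:
        logger.info(
            "%d zero-strength supernodes use the absorbing self-transition", zero.size
        )
        P[zero, zero] = 1.0
    # renormalize exactly to suppress fp drift before divergence computation
    P /= P.sum(axis=1, keepdims=True)
    return P


def node_distributions(sg: SummarizedGraph) -> np.ndarray:
    """k x k matrix whose row i is the one-step distribution of supernode i."""
    return _strength_distributions(sg.W_s)


def transition_matrix(sg: SummarizedGraph) -> TransitionMatrix:
    """Column-stochastic transition matrix: W_s rescaled by the strength of
    each (destination-column) supernode, diagonal counted once."""
    if sg.k < 1:
        raise ValueError("summarized graph must have at least one supernode")
    P = _strength_distributions(sg.W_s)
    # symmetry of W_s: column j of T equals row j of P
    return TransitionMatrix(sample_id=sg.sample_id, k=sg.k, T=P.T, partition=sg.partition)


def js_divergence(p: np.ndarray, q: np.ndarray) -> float:
    """Jensen-Shannon divergence in bits (base-2 logs, 0*log0 = 0)."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("distributions must have the same length")
    if np.any(p < 0) or np.any(q < 0):
        raise ValueError("distributions must be non-negative")
    if abs(p.sum() - 1.0) > 1e-9 or abs(q.sum() - 1.0) > 1e-9:
        raise ValueError("distributions must sum to 1")
    m = 0.5 * (p + q)
    j = 0.5 * (rel_entr(p, m).sum() + rel_entr(q, m).sum()) / _LN2
    return float(max(j, 0.0))


def js_distance(p: np.ndarray, q: np.ndarray) -> float:
    """Jensen-Shannon distance: sqrt of the base-2 divergence; in [0, 1]."""
    return float(np.sqrt(js_divergence(p, q)))


def _js_distance_rows(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Vectorized d_JS between corresponding rows of two stochastic matrices."""
    M = 0.5 * (P + Q)
    j = 0.5 * (rel_entr(P, M).sum(axis=1) + rel_entr(Q, M).sum(axis=1)) / _LN2
    return np.sqrt(np.clip(j, 0.0, None))


def m2_distance(Tp: TransitionMatrix, Tq: TransitionMatrix) -> float:
    """Average Jensen-Shannon distance between the per-supernode one-step
    distributions of two networks sharing a partition."""
    if Tp.k != Tq.k:
        raise ValueError(f"supernode counts differ: {Tp.k} vs {Tq.k}")
    if (
        Tp.partition is not None
        and Tq.partition is not None
        and not Tp.partition.same_partition(Tq.partition)
    ):
        raise ValueError("transition matrices come from different partitions")
    if Tp.k == 1:
        logger.warning("k=1 summarization: M2 is identically 0")
        return 0.0
    d = _js_distance_rows(Tp.distributions(), Tq.distributions())
    return float(np.clip(d.mean(), 0.0, 1.0))


def pairwise_distances(summaries: Sequence[SummarizedGraph]) -> DistanceMatrix:
    """M2 distance matrix over all sample pairs (upper triangle computed,
    mirrored by symmetry)."""
    if not summaries:
        raise ValueError("no summarized graphs supplied")
    ref = summaries[0]
    for sg in summaries[1:]:
        if sg.k != ref.k or not sg.partition.same_partition(ref.partition):
            raise ValueError(
                f"sample {sg.sample_id} does not share the reference partition"
            )
    dists = [node_distributions(sg) for sg in summaries]
    n = len(summaries)
    D = np.zeros((n, n))
    for p in range(n):
        for q in range(p + 1, n):
            d = float(np.clip(_js_distance_rows(dists[p], dists[q]).mean(), 0.0, 1.0))
            D[p, q] = D[q, p] = d
    return DistanceMatrix(sample_ids=[sg.sample_id for sg in summaries], D=D)
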