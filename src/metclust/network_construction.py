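"""Per-sample metabolite network construction.

Each patient sample is represented as a weighted simple graph on the
metabolites of the (filtered) model. For every reaction and every gene
catalyzing it, every (substrate, product) couple contributes one multigraph
edge weighted by that gene's expression in the sample. The multigraph is
then collapsed to a simple graph: parallel edges coming from the same
reaction are averaged (enzymes acting on one reaction are equally
important), and the per-reaction means for edges from different reactions
are summed (alternative reactions act as a Boolean OR between the same
metabolite pair).

All samples of a dataset share the same node set and edge structure; only
edge weights differ. Downstream analysis operates on the largest connected
component of that shared structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import product
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .model_io import ExpressionMatrix, MetabolicModel

logger = logging.getLogger(__name__)

__all__ = [
    "MultiEdge",
    "SampleMultigraph",
    "SampleGraph",
    "build_multigraph",
    "collapse_multigraph",
    "largest_connected_component",
    "induced_subgraph",
    "write_sample_graph",
    "read_sample_graph",
]


class MultiEdge(NamedTuple):
    source: str
    target: str
    reaction: str
    gene: str
    weight: float


@dataclass
class SampleMultigraph:
    """Intermediate multigraph: one edge per (reaction, gene, couple)."""

    sample_id: str
    nodes: tuple[str, ...]
    edges: list[MultiEdge]


@dataclass
class SampleGraph:
    """Weighted simple undirected graph for one sample.

    ``W`` is the symmetric zero-diagonal weight matrix over ``nodes``;
    ``structure`` is the boolean sample-independent edge structure (an edge
    may carry weight 0 when all its genes have zero expression, but it
    still exists structurally and is shared by every sample).
    """

    sample_id: str
    nodes: tuple[str, ...]
    W: np.ndarray
    structure: np.ndarray

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.structure = np.asarray(self.structure, dtype=bool)
        n = len(self.nodes)
        if self.W.shape != (n, n) or self.structure.shape != (n, n):
            raise ValueError("matrix shape does not match node count")
        if not np.allclose(self.W, self.W.T):
            raise ValueError("W must be symmetric")
        if np.any(np.diag(self.W) != 0):
            raise ValueError("W must have a zero diagonal")
        if np.any(self.W < 0):
            raise ValueError("W must be non-negative")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def total_weight(self) -> float:
        return float(self.W.sum())


def build_multigraph(
    model: MetabolicModel, expr: ExpressionMatrix, sample_id: str
) -> SampleMultigraph:
    """Expand the model into the per-sample multigraph: one edge per
    (reaction, catalyzing gene, substrate x product couple), weighted by
    the gene's expression in ``sample_id``.

    The model is expected to be pre-filtered (recurrent metabolites
    removed); uncatalyzed reactions and genes absent from the expression
    matrix contribute nothing. Self-couples (a metabolite that is both
    substrate and product of one reaction) are skipped.
    """
    if sample_id not in expr.samples:
        raise KeyError(f"sample {sample_id!r} not in expression matrix")
    edges: list[MultiEdge] = []
    n_missing = 0
    for r in model.reactions:
        genes = sorted(r.genes)
        present = [g for g in genes if g in expr]
        n_missing += len(genes) - len(present)
        if not present:
            continue
        couples = [(s, p) for s, p in product(r.substrates, r.products) if s != p]
        if not couples:
            continue
        for g in present:
            w = expr.value(g, sample_id)
            for s, p in couples:
                edges.append(MultiEdge(s, p, r.id, g, w))
    if n_missing:
        logger.info(
            "sample %s: %d gene occurrences absent from expression matrix",
            sample_id,
            n_missing,
        )
    return SampleMultigraph(sample_id=sample_id, nodes=model.node_ids, edges=edges)


def collapse_multigraph(mg: SampleMultigraph) -> SampleGraph:
    """Reduce a multigraph to a weighted simple graph.

    For each unordered node pair the collapsed weight is
    ``sum over reactions r of mean(parallel edge weights from r)``.
    A pair keeps a structural (possibly zero-weight) edge whenever at least
    one multigraph edge existed between its nodes.
    """
    index = {n: i for i, n in enumerate(mg.nodes)}
    n = len(mg.nodes)
    # (i, j, reaction) -> [sum, count] with i < j
    acc: dict[tuple[int, int, str], list[float]] = {}
    for e in mg.edges:
        i, j = index[e.source], index[e.target]
        if i > j:
            i, j = j, i
        key = (i, j, e.reaction)
        slot = acc.get(key)
        if slot is None:
            acc[key] = [e.weight, 1]
        else:
            slot[0] += e.weight
            slot[1] += 1
    W = np.zeros((n, n))
    structure = np.zeros((n, n), dtype=bool)
    for (i, j, _r), (total, count) in acc.items():
        mean = total / count
        W[i, j] += mean
        W[j, i] += mean
        structure[i, j] = structure[j, i] = True
    return SampleGraph(sample_id=mg.sample_id, nodes=mg.nodes, W=W, structure=structure)


def _component_labels(structure: np.ndarray) -> tuple[int, np.ndarray]:
    n_comp, labels = connected_components(
        csr_matrix(structure), directed=False, return_labels=True
    )
    return n_comp, labels


def largest_connected_component(g: SampleGraph) -> SampleGraph:
    """Induced subgraph on the largest component of the unweighted edge
    structure. Ties are broken toward the component containing the
    lexicographically smallest node id; discarded component sizes are
    logged."""
    if g.n_nodes == 0:
        raise ValueError("empty graph has no connected component")
    n_comp, labels = _component_labels(g.structure)
    sizes = np.bincount(labels, minlength=n_comp)
    best_size = sizes.max()
    candidates = np.flatnonzero(sizes == best_size)
    if len(candidates) > 1:
        # deterministic tie-break: component holding the smallest node id
        def smallest_member(c: int) -> str:
            return min(g.nodes[i] for i in np.flatnonzero(labels == c))

        winner = min(candidates, key=smallest_member)
    else:
        winner = candidates[0]
    discarded = sorted((int(s) for c, s in enumerate(sizes) if c != winner), reverse=True)
    if discarded:
        logger.info(
            "discarding %d smaller components (sizes %s)", len(discarded), discarded
        )
    keep = np.flatnonzero(labels == winner)
    return induced_subgraph(g, keep)


def induced_subgraph(g: SampleGraph, indices: Sequence[int]) -> SampleGraph:
    idx = np.asarray(indices, dtype=int)
    return SampleGraph(
        sample_id=g.sample_id,
        nodes=tuple(g.nodes[i] for i in idx),
        W=g.W[np.ix_(idx, idx)],
        structure=g.structure[np.ix_(idx, idx)],
    )


# ---------------------------------------------------------------------------
# persistence: weighted edge list + node-order sidecar


def write_sample_graph(g: SampleGraph, edges_path: str | Path, nodes_path: str | Path) -> None:
    """Persist as a TSV edge list (node_a, node_b, weight) plus a node-order
    sidecar guaranteeing cross-sample alignment. Structural zero-weight
    edges are written too."""
    with open(nodes_path, "w") as fh:
        for nid in g.nodes:
            fh.write(f"{nid}\n")
    iu = np.triu_indices(g.n_nodes, k=1)
    with open(edges_path, "w") as fh:
        fh.write("node_a\tnode_b\tweight\n")
        for i, j in zip(*iu):
            if g.structure[i, j]:
                fh.write(f"{g.nodes[i]}\t{g.nodes[j]}\t{float(g.W[i, j])!r}\n")


def read_sample_graph(
    edges_path: str | Path, nodes_path: str | Path, sample_id: str
) -> SampleGraph:
    nodes = tuple(
        line.strip() for line in Path(nodes_path).read_text().splitlines() if line.strip()
    )
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    W = np.zeros((n, n))
    structure = np.zeros((n, n), dtype=bool)
    with open(edges_path) as fh:
        header = fh.readline()
        if not header.startswith("node_a"):
            raise ValueError(f"{edges_path}: missing edge-list header")
        for line in fh:
            a, b, w = line.rstrip("\n").split("\t")
            i, j = index[a], index[b]
            W[i, j] = W[j, i] = float(w)
            structure[i, j] = structure[j, i] = True
    return SampleGraph(sample_id=sample_id, nodes=nodes, W=W, structure=structure)
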