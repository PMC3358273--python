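"""TRIBE-style Markov clustering of domain instances.

Directed E-values become a symmetric weighted graph (weight = mean of
-log10 E over the two directions, capped and floored), self-loops are
added, and the graph is partitioned by the Markov Cluster algorithm:
alternate expansion (matrix power of the column-stochastic flow matrix)
and inflation (entrywise power + column renormalisation) until the flow
reaches a fixed point, then read clusters off the connected components of
the limit matrix's nonzero structure.

Inflation controls granularity; the pipeline default is 5, a fine-grained
setting suited to separating specificity-bearing domain families.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from .domain_extraction import DomainInstance
from .sequence_io import ClusterSet, Model
from .similarity import (DEFAULT_EVALUE_CUTOFF, ScoringScheme, SimilarityEdge,
                         local_score, score_to_evalue)

logger = logging.getLogger(__name__)

#: -log10 weight assigned to an E-value of exactly zero
DEFAULT_WEIGHT_CAP = 200.0
#: floor for the self-loop of an isolated node (keeps its column stochastic)
MIN_SELF_LOOP = 1.0


@dataclass
class SimilarityGraph:
    """Symmetric weighted similarity graph over domain instances.

    ``ids`` is sorted, so the matrix layout (and everything downstream)
    is invariant to the order edges or nodes were supplied in.
    """

    ids: list[str]
    W: np.ndarray

    @property
    def n(self) -> int:
        return len(self.ids)


def build_graph(
    edges: Iterable[SimilarityEdge],
    nodes: Iterable[str] | None = None,
    weight_cap: float = DEFAULT_WEIGHT_CAP,
) -> SimilarityGraph:
    """Symmetrise directed E-value edges into a weighted graph.

    Each direction contributes ``-log10(evalue)`` (``weight_cap`` for an
    E-value of zero or below ``10**-weight_cap``); the undirected weight is
    the mean over the directions present, floored at 0.  Self-loops are set
    to each node's maximum incident weight, with a floor of 1 so isolated
    nodes still have a stochastic-izable column.

    ``nodes`` lists instance ids that must appear even if no edge touches
    them (isolated instances form singleton clusters).
    """
    per_pair: dict[tuple[str, str], list[float]] = {}
    node_set: set[str] = set(nodes) if nodes is not None else set()
    for e in edges:
        node_set.add(e.a_id)
        node_set.add(e.b_id)
        if e.a_id == e.b_id:
            continue
        if e.evalue <= 10.0 ** (-weight_cap):
            w = weight_cap
        else:
            w = min(-math.log10(e.evalue), weight_cap)
        key = (e.a_id, e.b_id) if e.a_id < e.b_id else (e.b_id, e.a_id)
        per_pair.setdefault(key, []).append(w)

    ids = sorted(node_set)
    index = {node: i for i, node in enumerate(ids)}
    W = np.zeros((len(ids), len(ids)))
    for (a, b), weights in per_pair.items():
        w = max(0.0, sum(weights) / len(weights))
        W[index[a], index[b]] = w
        W[index[b], index[a]] = w
    loops = np.maximum(W.max(axis=1, initial=0.0), MIN_SELF_LOOP)
    np.fill_diagonal(W, loops)
    return SimilarityGraph(ids=ids, W=W)


def _normalize_columns(M: np.ndarray) -> np.ndarray:
    return M / M.sum(axis=0, keepdims=True)


def mcl(
    graph: SimilarityGraph,
    inflation: float = 5.0,
    expansion: int = 2,
    prune_below: float = 1e-5,
    max_iter: int = 200,
    tol: float = 1e-8,
    model: Model | None = None,
    on_iteration: Callable[[np.ndarray], None] | None = None,
) -> ClusterSet:
    """Partition the graph with the Markov Cluster algorithm.

    Iterates expansion (``M**expansion`` in the matrix-product sense),
    inflation (entrywise power then column renormalisation) and pruning of
    entries below ``prune_below`` until the flow matrix changes by less
    than ``tol``; clusters are the connected components of the nonzero
    structure of the limit matrix.  Non-convergence within ``max_iter``
    returns the current partition with ``converged=False`` and a warning
    in the log.

    ``on_iteration`` receives the flow matrix after every iteration
    (diagnostics; column sums are 1 at each call).
    """
    if inflation <= 1:
        raise ValueError("inflation must exceed 1")
    if graph.n == 0:
        return ClusterSet(assignments={}, model=model)
    M = _normalize_columns(graph.W.astype(float))
    converged = False
    for _ in range(max_iter):
        M_next = np.linalg.matrix_power(M, expansion)
        np.power(M_next, inflation, out=M_next)
        M_next = _normalize_columns(M_next)
        M_next[M_next < prune_below] = 0.0
        M_next = _normalize_columns(M_next)
        if on_iteration is not None:
            on_iteration(M_next)
        delta = np.abs(M_next - M).max()
        M = M_next
        if delta < tol:
            converged = True
            break
    if not converged:
        logger.warning("MCL did not converge within %d iterations", max_iter)
    structure = sp.csr_matrix((M > 0) | (M.T > 0))
    _, labels = connected_components(structure, directed=False)
    # dense cluster ids ordered by first appearance along the sorted node list
    relabel: dict[int, int] = {}
    assignments: dict[str, int] = {}
    for node, raw in zip(graph.ids, labels):
        if raw not in relabel:
            relabel[raw] = len(relabel)
        assignments[node] = relabel[raw]
    return ClusterSet(assignments=assignments, model=model, converged=converged)


@dataclass(frozen=True)
class NearestClusterResult:
    """Outcome of routing a query sequence to its most similar cluster."""

    cluster_id: int | None
    best_hit_id: str | None
    evalue: float | None

    @property
    def assignable(self) -> bool:
        return self.cluster_id is not None


UNASSIGNABLE = NearestClusterResult(None, None, None)


def nearest_cluster(
    query_subsequence: str,
    instances: Sequence[DomainInstance],
    clusters: ClusterSet,
    scheme: ScoringScheme | None = None,
    evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF,
) -> NearestClusterResult:
    """Cluster of the database instance most similar to a novel query.

    Mirrors a local database search of the query against all clustered
    instances: the best hit is the one with the smallest E-value, ties
    broken by higher raw score then lexicographically smaller instance id.
    With no hit at or below ``evalue_cutoff`` the query is unassignable
    (an explicit result, not an exception).
    """
    scheme = scheme or ScoringScheme()
    if not query_subsequence:
        raise ValueError("empty query sequence")
    n_db = sum(len(i) for i in instances)
    best: tuple[float, float, str] | None = None  # (evalue, -score, id)
    for inst in sorted(instances, key=lambda i: i.instance_id):
        if inst.instance_id not in clusters.assignments:
            continue
        score = local_score(query_subsequence, inst.subsequence, scheme)
        evalue = score_to_evalue(score, len(query_subsequence), n_db, scheme)
        if evalue > evalue_cutoff:
            continue
        key = (evalue, -float(score), inst.instance_id)
        if best is None or key < best:
            best = key
    if best is None:
        return UNASSIGNABLE
    evalue, neg_score, hit_id = best
    return NearestClusterResult(
        cluster_id=clusters.assignments[hit_id],
        best_hit_id=hit_id,
        evalue=evalue,
    )
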