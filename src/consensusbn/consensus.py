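"""Consensus networks: merge a DAG ensemble, threshold by resolution, classify.

The ensemble's directed adjacency matrices are summed edge-wise, then
direction is discarded by adding the matrix to its transpose, giving an
undirected graph whose edge weight counts the supporting DAGs.  An edge's
*resolution* is its weight divided by the largest edge weight in the
network; thresholding the resolution trades a broad, inclusive edge set
(low threshold) against a narrow, well-supported one (high threshold).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from consensusbn.k2 import DirectedNetwork

__all__ = [
    "ConsensusNetwork",
    "EdgeClassification",
    "accumulate",
    "symmetrize",
    "consensus_from_ensemble",
    "edge_resolution",
    "filter_by_resolution",
    "classify_edges",
]

Edge = tuple[int, int]


@dataclass
class ConsensusNetwork:
    """Symmetric non-negative integer edge weights over gene groups."""

    weights: np.ndarray
    n_networks: int
    group_names: list[str]

    def __post_init__(self) -> None:
        W = np.asarray(self.weights, dtype=np.int64)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError("weights must be square")
        if self.group_names and len(self.group_names) != W.shape[0]:
            raise ValueError("group_names length does not match matrix size")
        if not self.group_names:
            self.group_names = [f"G{i}" for i in range(W.shape[0])]
        if (W < 0).any():
            raise ValueError("weights must be non-negative")
        if np.diagonal(W).any():
            raise ValueError("diagonal must be zero")
        if not np.array_equal(W, W.T):
            raise ValueError("weights must be symmetric")
        if W.size and W.max() > self.n_networks:
            raise ValueError("an edge weight exceeds the ensemble size")
        self.weights = W

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def max_weight(self) -> int:
        return int(self.weights.max())

    def nonzero_edges(self) -> list[Edge]:
        """Edges with positive weight, canonically oriented (i < j)."""
        iu = np.triu_indices(self.n_nodes, k=1)
        mask = self.weights[iu] > 0
        return list(zip(iu[0][mask].tolist(), iu[1][mask].tolist()))


def accumulate(networks: Sequence[DirectedNetwork]) -> np.ndarray:
    """Sum the ensemble's adjacency matrices into a directed weight matrix.

    Entry (p, c) counts the DAGs containing edge p -> c.
    """
    if not networks:
        raise ValueError("cannot accumulate an empty ensemble")
    n = networks[0].n_nodes
    total = np.zeros((n, n), dtype=np.int64)
    for net in networks:
        if net.n_nodes != n:
            raise ValueError("all networks must share the same node set")
        total += net.adjacency
    return total


def symmetrize(
    directed_weights: np.ndarray,
    n_networks: int | None = None,
    group_names: Sequence[str] | None = None,
) -> ConsensusNetwork:
    """Discard edge direction: undirected weight = w(a->b) + w(b->a).

    ``n_networks`` defaults to the maximum resulting weight, the tightest
    bound the matrix itself supports.
    """
    D = np.asarray(directed_weights)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("directed weight matrix must be square")
    if (D < 0).any():
        raise ValueError("weights must be non-negative")
    if np.diagonal(D).any():
        raise ValueError("diagonal must be zero")
    W = D + D.T
    if n_networks is None:
        n_networks = int(W.max())
    return ConsensusNetwork(
        weights=W,
        n_networks=n_networks,
        group_names=list(group_names) if group_names is not None else [],
    )


def consensus_from_ensemble(
    networks: Sequence[DirectedNetwork],
    group_names: Sequence[str] | None = None,
) -> ConsensusNetwork:
    """Convenience: accumulate then symmetrize, recording the ensemble size."""
    return symmetrize(accumulate(networks), n_networks=len(networks),
                      group_names=group_names)


def _check_nonzero(network: ConsensusNetwork) -> int:
    mx = network.max_weight
    if mx == 0:
        raise ValueError("resolution is undefined for an all-zero network")
    return mx


def edge_resolution(network: ConsensusNetwork, edge: Edge) -> float:
    """Edge weight divided by the network's largest edge weight, in [0, 1]."""
    mx = _check_nonzero(network)
    a, b = edge
    if a == b:
        raise ValueError("self-edges have no resolution")
    return float(network.weights[a, b]) / mx


def filter_by_resolution(
    network: ConsensusNetwork,
    threshold: float,
    strict: bool = False,
) -> set[Edge]:
    """Edges whose resolution meets the threshold, as (i < j) pairs.

    By default an edge is kept when resolution >= threshold, so the
    maximal-weight edge survives a threshold of 1.0; ``strict=True``
    switches to a strict > comparison.
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must lie in [0, 1]")
    mx = _check_nonzero(network)
    iu = np.triu_indices(network.n_nodes, k=1)
    res = network.weights[iu] / mx
    nonzero = network.weights[iu] > 0
    keep = (res > threshold) if strict else (res >= threshold)
    keep &= nonzero
    return set(zip(iu[0][keep].tolist(), iu[1][keep].tolist()))


@dataclass(frozen=True)
class EdgeClassification:
    """One consensus edge labelled against reference pathway edge sets."""

    edge: Edge
    label: str  # 'conserved' | 'novel' | 'cross-pathway'


def _canon(edge: Iterable[int]) -> Edge:
    a, b = edge
    return (min(a, b), max(a, b))


def classify_edges(
    edges: Iterable[Edge],
    reference_edges: Mapping[str, Iterable[Edge]],
    node_pathway: Mapping[int, str],
) -> list[EdgeClassification]:
    """Label consensus edges as conserved, novel, or cross-pathway.

    An edge whose endpoints share a pathway is *conserved* if that pathway's
    reference edge set contains it and *novel* otherwise; an edge joining
    two pathways is *cross-pathway*.  Negative controls get their own
    pathway label, so a control-control edge is judged against an (empty)
    control reference rather than being called cross-pathway.
    """
    refs = {p: {_canon(e) for e in es} for p, es in reference_edges.items()}
    out: list[EdgeClassification] = []
    for edge in sorted(_canon(e) for e in edges):
        a, b = edge
        for node in edge:
            if node not in node_pathway:
                raise ValueError(f"node {node} has no pathway label")
        pa, pb = node_pathway[a], node_pathway[b]
        if pa != pb:
            label = "cross-pathway"
        elif edge in refs.get(pa, set()):
            label = "conserved"
        else:
            label = "novel"
        out.append(EdgeClassification(edge=edge, label=label))
    return out
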