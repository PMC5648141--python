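"""K2 structure learning with the Cooper-Herskovits marginal-likelihood score.

Given a topological ordering of the nodes, K2 considers each node in turn and
greedily adds the single predecessor whose addition most increases the local
marginal likelihood, stopping when no candidate strictly improves the score
or the parent cap (default 5) is reached.  Restricting parents to
predecessors in the ordering guarantees acyclicity and reduces the search
space enough to make large ensembles affordable.

For a binary node with parent set P, r = 2 states, q = 2^{|P|} parent
configurations, N_jk the number of records with parent configuration j and
node state k, and N_j = sum_k N_jk, the local score is

    prod_j  (r-1)! / (N_j + r - 1)!  *  prod_k N_jk!

(the uniform-Dirichlet marginal likelihood), evaluated in log space with
log-gamma.  Parent configurations never observed in the data contribute a
factor of 1 and drop out.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.special import gammaln

from consensusbn.corpus import PriorKnowledgeMatrix

__all__ = [
    "TopologicalOrder",
    "K2Config",
    "DirectedNetwork",
    "local_log_score",
    "k2_learn",
    "generate_orders",
    "learn_ensemble",
]

_R = 2  # binary variables throughout


@dataclass(frozen=True)
class TopologicalOrder:
    """A node permutation; parents of a node must precede it."""

    sequence: tuple[int, ...]

    def __init__(self, sequence: Sequence[int]):
        seq = tuple(int(i) for i in sequence)
        if sorted(seq) != list(range(len(seq))):
            raise ValueError("sequence must be a permutation of 0..n-1")
        object.__setattr__(self, "sequence", seq)

    @property
    def start_node(self) -> int:
        return self.sequence[0]

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class K2Config:
    """K2 search settings: parent cap (5 in the reference protocol) and seed."""

    max_parents: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_parents < 1:
            raise ValueError("max_parents must be >= 1")


@dataclass(frozen=True)
class DirectedNetwork:
    """One learned DAG: adjacency[p, c] == 1 means edge p -> c."""

    adjacency: np.ndarray
    order: TopologicalOrder

    def __post_init__(self) -> None:
        adj = np.asarray(self.adjacency, dtype=np.int8)
        object.__setattr__(self, "adjacency", adj)
        n = len(self.order)
        if adj.shape != (n, n):
            raise ValueError("adjacency shape does not match order length")
        if np.diagonal(adj).any():
            raise ValueError("self-loops are not allowed")
        pos = np.empty(n, dtype=int)
        pos[list(self.order.sequence)] = np.arange(n)
        parents, children = np.nonzero(adj)
        if np.any(pos[parents] >= pos[children]):
            raise ValueError("every parent must precede its child in the order")

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    def edges(self) -> list[tuple[int, int]]:
        return [(int(p), int(c)) for p, c in zip(*np.nonzero(self.adjacency))]


def _validate_data(data: PriorKnowledgeMatrix) -> np.ndarray:
    X = np.asarray(data.values)
    if X.shape[0] < 1:
        raise ValueError("data must have at least one row")
    if not np.isin(X, (0, 1)).all():
        raise ValueError("data must be strictly binary")
    return X.astype(np.int64)


def _log_score_from_codes(child: np.ndarray, parent_code: np.ndarray) -> float:
    """Score a node given precomputed parent-configuration codes per record.

    ``parent_code`` assigns each record an integer identifying its parent
    configuration; only observed configurations enter the product.
    """
    joint = parent_code * _R + child
    counts = np.bincount(joint)
    n_codes = (len(counts) + _R - 1) // _R * _R
    njk = np.zeros(n_codes, dtype=np.int64)
    njk[: len(counts)] = counts
    njk = njk.reshape(-1, _R)
    nj = njk.sum(axis=1)
    # gammaln(r) - gammaln(nj + r) + sum_k gammaln(njk + 1); empty configs
    # contribute exactly zero, so no masking is needed.
    return float(
        np.sum(gammaln(_R) - gammaln(nj + _R) + gammaln(njk + 1).sum(axis=1))
    )


def local_log_score(
    node: int,
    parents: Iterable[int],
    data: PriorKnowledgeMatrix,
) -> float:
    """Log marginal likelihood of ``node`` given ``parents`` under the data.

    Deterministic; raises for an out-of-range node or a node listed among
    its own parents.
    """
    X = _validate_data(data)
    n = X.shape[1]
    parents = [int(p) for p in parents]
    if not (0 <= node < n):
        raise IndexError(f"node {node} out of range for {n} columns")
    if any(not (0 <= p < n) for p in parents):
        raise IndexError("parent index out of range")
    if node in parents:
        raise ValueError("a node cannot be its own parent")
    code = np.zeros(X.shape[0], dtype=np.int64)
    for p in parents:
        code = code * 2 + X[:, p]
    return _log_score_from_codes(X[:, node], code)


def k2_learn(
    order: TopologicalOrder,
    data: PriorKnowledgeMatrix,
    config: K2Config = K2Config(),
) -> DirectedNetwork:
    """Learn one DAG by the K2 greedy search along ``order``.

    At each node, the predecessor giving the largest strict increase in the
    local log score is added until no candidate improves the score or
    ``config.max_parents`` is reached.  Score ties between candidates are
    broken toward the lowest node index, so the result is deterministic.
    """
    X = _validate_data(data)
    n = X.shape[1]
    if len(order) != n:
        raise ValueError(
            f"order covers {len(order)} nodes but data has {n} columns"
        )
    adj = np.zeros((n, n), dtype=np.int8)
    cols = {j: X[:, j] for j in range(n)}
    for pos, node in enumerate(order.sequence):
        child = cols[node]
        code = np.zeros(X.shape[0], dtype=np.int64)
        best = _log_score_from_codes(child, code)
        parents: list[int] = []
        candidates = sorted(order.sequence[:pos])
        while len(parents) < config.max_parents and candidates:
            gain_best = None
            pick = None
            for cand in candidates:
                trial = _log_score_from_codes(child, code * 2 + cols[cand])
                if gain_best is None or trial > gain_best:
                    gain_best = trial
                    pick = cand
            if gain_best is None or gain_best <= best:
                break
            best = gain_best
            parents.append(pick)
            candidates.remove(pick)
            code = code * 2 + cols[pick]
        for p in parents:
            adj[p, node] = 1
    return DirectedNetwork(adjacency=adj, order=order)


def generate_orders(
    n_nodes: int,
    start_node: int,
    count: int,
    seed: int,
) -> list[TopologicalOrder]:
    """Random topological orderings pinned to a given start node.

    Each ordering places ``start_node`` first and uniformly permutes the
    remaining nodes; the list is reproducible for a fixed seed.
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    if not (0 <= start_node < n_nodes):
        raise ValueError("start_node out of range")
    rng = np.random.default_rng(seed)
    rest = np.array([i for i in range(n_nodes) if i != start_node])
    orders = []
    for _ in range(count):
        perm = rng.permutation(rest) if len(rest) else rest
        orders.append(TopologicalOrder((start_node, *perm.tolist())))
    return orders


def learn_ensemble(
    data: PriorKnowledgeMatrix,
    topologies_per_start: int,
    config: K2Config = K2Config(),
) -> list[DirectedNetwork]:
    """Learn ``n_groups * topologies_per_start`` DAGs, one per random order.

    Orderings begin from every node in turn so no node is systematically
    denied parents by its position.  The computation is a pure map over the
    order list: results are identical however the orders are scheduled.
    """
    if topologies_per_start < 1:
        raise ValueError("topologies_per_start must be >= 1")
    n = data.n_groups
    if n < 2:
        raise ValueError("data must have at least two columns")
    networks: list[DirectedNetwork] = []
    for start in range(n):
        # per-start-node substream: reproducible and order-independent
        order_seed = int(
            np.random.SeedSequence([config.seed, start]).generate_state(1)[0]
        ) & 0x7FFFFFFF
        for order in generate_orders(n, start, topologies_per_start, int(order_seed)):
            networks.append(k2_learn(order, data, config))
    return networks
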