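"""Synthetic evidence with known ground truth.

Two generators back the test suite and the acceptance experiments:

* ``sample_records`` draws binary occurrence records ancestrally from a
  planted DAG with explicit conditional probability tables, emulating a
  prior-knowledge matrix whose dependency structure is known exactly.
* ``make_corpus`` writes small synthetic abstracts that embed gene-group
  member terms inside chosen delimiter contexts, so the full mining path
  (text -> matrix) can be round-tripped against a designed presence matrix.

The planted models use strong conditionals (a node is likely on when a
parent is on, unlikely otherwise), mimicking the tight co-mention patterns
of genes that genuinely interact; they do not reproduce the extreme
sparsity or long-tailed group popularity of real PubMed evidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from consensusbn.corpus import AbstractRecord, GeneGroup, PriorKnowledgeMatrix

__all__ = [
    "PlantedModel",
    "CorpusSpec",
    "sample_records",
    "make_corpus",
    "chain_fork_collider_model",
    "random_pathway_model",
    "random_corpus_spec",
    "VALID_CONTEXTS",
]


@dataclass
class PlantedModel:
    """A ground-truth Bayesian network over binary occurrence variables.

    ``cpts[node]`` gives P(node = 1) for every configuration of the node's
    parents; configurations are indexed by the integer whose bit k is the
    state of the k-th parent in increasing node order.  Root nodes have a
    single entry (their marginal).
    """

    adjacency: np.ndarray  # (n, n), entry (p, c) = 1 for edge p -> c
    cpts: dict[int, np.ndarray]
    n_records: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        A = np.asarray(self.adjacency, dtype=np.int8)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("adjacency must be square")
        self.adjacency = A
        G = nx.DiGraph(A)
        if not nx.is_directed_acyclic_graph(G):
            raise ValueError("planted structure must be acyclic")
        n = A.shape[0]
        for node in range(n):
            parents = self.parents(node)
            cpt = np.asarray(self.cpts[node], dtype=float)
            if cpt.shape != (2 ** len(parents),):
                raise ValueError(
                    f"node {node}: CPT must have 2^{len(parents)} entries"
                )
            if ((cpt < 0) | (cpt > 1)).any():
                raise ValueError(f"node {node}: probabilities outside [0, 1]")
            self.cpts[node] = cpt
        if self.n_records < 1:
            raise ValueError("n_records must be >= 1")

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    def parents(self, node: int) -> list[int]:
        return [int(p) for p in np.nonzero(self.adjacency[:, node])[0]]

    def skeleton(self) -> set[tuple[int, int]]:
        """Undirected ground-truth edges as (i < j) pairs."""
        ps, cs = np.nonzero(self.adjacency)
        return {(min(p, c), max(p, c)) for p, c in zip(ps.tolist(), cs.tolist())}

    def marginals(self) -> np.ndarray:
        """Exact P(node = 1) per node by joint enumeration (small n only)."""
        n = self.n_nodes
        if n > 20:
            raise ValueError("exact marginals require <= 20 nodes")
        states = (np.arange(2 ** n)[:, None] >> np.arange(n)) & 1
        logp = np.zeros(2 ** n)
        for node in range(n):
            pars = self.parents(node)
            cfg = np.zeros(2 ** n, dtype=np.int64)
            for k, p in enumerate(pars):
                cfg |= states[:, p] << k
            p1 = self.cpts[node][cfg]
            logp += np.where(states[:, node] == 1,
                             np.log(np.clip(p1, 1e-300, None)),
                             np.log(np.clip(1 - p1, 1e-300, None)))
        prob = np.exp(logp)
        return (prob[:, None] * states).sum(axis=0)


def sample_records(
    model: PlantedModel,
    apply_inclusion_rule: bool = False,
    id_prefix: str = "SYN",
) -> PriorKnowledgeMatrix:
    """Ancestral sampling: one binary record per synthetic publication.

    Records emulate the matrix *after* construction, so the >= 2-ones
    inclusion rule is not applied unless ``apply_inclusion_rule`` is set.
    """
    rng = np.random.default_rng(model.seed)
    n, m = model.n_nodes, model.n_records
    X = np.zeros((m, n), dtype=np.int8)
    order = list(nx.topological_sort(nx.DiGraph(model.adjacency)))
    for node in order:
        pars = model.parents(node)
        cfg = np.zeros(m, dtype=np.int64)
        for k, p in enumerate(pars):
            cfg |= X[:, p].astype(np.int64) << k
        p1 = model.cpts[node][cfg]
        X[:, node] = rng.random(m) < p1
    ids = [f"{id_prefix}{i:07d}" for i in range(m)]
    names = [f"G{j}" for j in range(n)]
    if apply_inclusion_rule:
        keep = X.sum(axis=1) >= 2
        X = X[keep]
        ids = [i for i, k in zip(ids, keep) if k]
    return PriorKnowledgeMatrix(row_ids=ids, group_names=names, values=X)


def chain_fork_collider_model(
    n_records: int = 5000,
    seed: int = 0,
    p_hi: float = 0.9,
    p_lo: float = 0.1,
) -> PlantedModel:
    """The default 10-node benchmark: chain, fork, and collider motifs.

    Edges: 0->1->2, a fork 2->3 / 2->4, a collider 3->5<-4, then a tail
    chain 5->6->7->8->9.  Conditionals are strong (``p_hi`` when any parent
    is on, ``p_lo`` otherwise), making the skeleton recoverable from a few
    thousand records.
    """
    edges = [(0, 1), (1, 2), (2, 3), (2, 4), (3, 5), (4, 5),
             (5, 6), (6, 7), (7, 8), (8, 9)]
    n = 10
    A = np.zeros((n, n), dtype=np.int8)
    for p, c in edges:
        A[p, c] = 1
    cpts: dict[int, np.ndarray] = {}
    for node in range(n):
        k = int(A[:, node].sum())
        if k == 0:
            cpts[node] = np.array([0.5])
        else:
            # "any parent on" gate with strong conditionals
            cfg = np.arange(2 ** k)
            any_on = cfg > 0
            cpts[node] = np.where(any_on, p_hi, p_lo)
    return PlantedModel(adjacency=A, cpts=cpts, n_records=n_records, seed=seed)


def random_pathway_model(
    n_nodes: int,
    n_records: int = 5000,
    seed: int = 0,
    mean_parents: float = 1.3,
    max_parents: int = 3,
    p_hi: float = 0.85,
    p_lo: float = 0.1,
    p_root: float = 0.3,
) -> PlantedModel:
    """A random planted DAG emulating a pathway-scale dependency structure.

    Stands in for literature evidence over ``n_nodes`` gene groups when the
    real prior-knowledge matrices are not available: nodes are ordered
    0..n-1, each node draws up to ``max_parents`` parents from its
    predecessors (about ``mean_parents`` on average), and conditionals are
    strong ("any parent on" -> ``p_hi``, else ``p_lo``).  Deterministic for
    a fixed seed.
    """
    if n_nodes < 2:
        raise ValueError("need at least two nodes")
    rng = np.random.default_rng(seed)
    A = np.zeros((n_nodes, n_nodes), dtype=np.int8)
    for child in range(1, n_nodes):
        avail = child
        k = min(avail, max_parents, rng.poisson(mean_parents))
        k = max(k, 1 if child == 1 else 0)
        if k > 0:
            parents = rng.choice(avail, size=k, replace=False)
            A[parents, child] = 1
    cpts: dict[int, np.ndarray] = {}
    for node in range(n_nodes):
        k = int(A[:, node].sum())
        if k == 0:
            cpts[node] = np.array([p_root])
        else:
            cfg = np.arange(2 ** k)
            cpts[node] = np.where(cfg > 0, p_hi, p_lo)
    return PlantedModel(adjacency=A, cpts=cpts, n_records=n_records, seed=seed)


# ---------------------------------------------------------------------------
# synthetic corpora for the mining path

_FILLER = (
    "the of and in was were with for this that observed measured role "
    "effect cells tissue levels results study analysis model data using "
    "between among increased decreased signaling response expression"
).split()

#: delimiter contexts the matcher must honor: (prefix, suffix) pairs
VALID_CONTEXTS: tuple[tuple[str, str], ...] = (
    (" ", " "), ("(", ")"), ("[", "]"), ("-", "-"),
    (" ", ","), (" ", "."), (" ", ":"), (" ", ";"),
)


@dataclass
class CorpusSpec:
    """Design for a synthetic corpus: which groups appear in which document.

    ``design`` is a boolean matrix (n_docs x n_groups); document d embeds
    one member of group g iff design[d, g].  ``contexts`` supplies the
    (prefix, suffix) delimiter pairs to wrap embedded terms in.
    """

    groups: list[GeneGroup]
    design: np.ndarray
    contexts: Sequence[tuple[str, str]] = VALID_CONTEXTS
    seed: int = 0

    def __post_init__(self) -> None:
        D = np.asarray(self.design, dtype=bool)
        if D.ndim != 2 or D.shape[1] != len(self.groups):
            raise ValueError("design must be n_docs x n_groups")
        if D.shape[0] < 1:
            raise ValueError("at least one document is required")
        for g in self.groups:
            if not g.members:
                raise ValueError(f"group {g.name!r} has no members")
        self.design = D


def random_corpus_spec(
    groups: Sequence[GeneGroup],
    n_docs: int,
    seed: int = 0,
    p_present: float = 0.4,
) -> CorpusSpec:
    """A randomized co-mention design with independent group presence."""
    rng = np.random.default_rng(seed)
    design = rng.random((n_docs, len(groups))) < p_present
    return CorpusSpec(groups=list(groups), design=design, seed=seed)


def make_corpus(spec: CorpusSpec) -> list[AbstractRecord]:
    """Emit synthetic abstracts realizing the co-mention design.

    Each designated group contributes one randomly chosen member wrapped in
    a randomly chosen delimiter context, interleaved with filler words that
    contain no member term as a substring, so mining the corpus with
    ``build_prior_matrix`` reproduces exactly the designed presence matrix
    (restricted to rows with >= 2 groups).
    """
    rng = np.random.default_rng(spec.seed)
    members_lower = [m.lower() for g in spec.groups for m in g.members]
    filler = [
        w for w in _FILLER
        if not any(m in w or w in m for m in members_lower)
    ]
    records: list[AbstractRecord] = []
    for d in range(spec.design.shape[0]):
        words: list[str] = list(rng.choice(filler, size=5))
        for g_idx in np.nonzero(spec.design[d])[0]:
            group = spec.groups[g_idx]
            member = group.members[rng.integers(len(group.members))]
            prefix, suffix = spec.contexts[rng.integers(len(spec.contexts))]
            words.append(f"{prefix}{member}{suffix}")
            words.extend(rng.choice(filler, size=3))
        title = " ".join(words[:4])
        abstract = " ".join(words[4:])
        records.append(
            AbstractRecord(pub_id=f"SYNPUB{d:06d}", title=title, abstract=abstract)
        )
    return records
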