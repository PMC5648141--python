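import numpy as np
import pytest

from consensusbn import (
    AbstractRecord,
    GeneGroup,
    PriorKnowledgeMatrix,
)


@pytest.fixture
def jak_groups():
    """Three small gene groups with alias lists, JAK-STAT style."""
    return [
        GeneGroup("JAK", ["JAK1", "JAK2", "TYK2"], node_index=0),
        GeneGroup("STAT", ["STAT3", "STAT5A"], node_index=1),
        GeneGroup("SOCS", ["SOCS1", "CIS"], node_index=2),
    ]


@pytest.fixture
def small_corpus():
    """Hand-written records with known group mentions.

    rec1 mentions JAK+STAT, rec2 only JAK, rec3 all three, rec4 two members
    of the same group only, rec5 nothing.
    """
    return [
        AbstractRecord("p1", "Activation of (STAT3) signaling",
                       "JAK2 phosphorylates the receptor."),
        AbstractRecord("p2", "JAK1 in development", "A kinase study."),
        AbstractRecord("p3", "STAT5A and SOCS1 feedback",
                       "TYK2-mediated loops were measured."),
        AbstractRecord("p4", "JAK1 and JAK2 redundancy", "Murine knockouts."),
        AbstractRecord("p5", "An unrelated cardiology report", "No genes here."),
    ]


@pytest.fixture
def tiny_matrix():
    """Six records over three binary columns, fixed by hand."""
    values = np.array(
        [
            [0, 0, 1],
            [1, 1, 0],
            [1, 1, 1],
            [0, 0, 0],
            [1, 1, 0],
            [0, 1, 1],
        ],
        dtype=np.int8,
    )
    return PriorKnowledgeMatrix(
        row_ids=[f"r{i}" for i in range(6)],
        group_names=["A", "B", "C"],
        values=values,
    )


def pure_python_local_score(node, parents, values):
    """Factorial-form oracle for the uniform-Dirichlet marginal likelihood.

    Independent of the package implementation: groups records by observed
    parent configuration and evaluates (r-1)! * prod_k N_jk! / (N_j+r-1)!
    per configuration with exact integer factorials.
    """
    import math
    from collections import Counter
    from fractions import Fraction

    r = 2
    configs = {}
    for row in values:
        key = tuple(int(row[p]) for p in parents)
        configs.setdefault(key, Counter())[int(row[node])] += 1
    total = Fraction(1)
    for counter in configs.values():
        nj = sum(counter.values())
        term = Fraction(math.factorial(r - 1), math.factorial(nj + r - 1))
        for k in range(r):
            term *= math.factorial(counter.get(k, 0))
        total *= term
    return math.log(total)


def exhaustive_best_parents(node, predecessors, values, max_parents):
    """Brute-force oracle: the best-scoring order-respecting parent set."""
    from itertools import combinations

    best_score = pure_python_local_score(node, (), values)
    best_set = ()
    for k in range(1, min(max_parents, len(predecessors)) + 1):
        for combo in combinations(sorted(predecessors), k):
            s = pure_python_local_score(node, combo, values)
            if s > best_score:
                best_score, best_set = s, combo
    return best_set, best_score
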