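"""K2 scoring and greedy search against exact factorial/brute-force oracles."""

import itertools
import math

import numpy as np
import pytest

from consensusbn import (
    DirectedNetwork,
    K2Config,
    PriorKnowledgeMatrix,
    TopologicalOrder,
    generate_orders,
    k2_learn,
    learn_ensemble,
    local_log_score,
)
from conftest import exhaustive_best_parents, pure_python_local_score


def _pkm(values):
    values = np.asarray(values, dtype=np.int8)
    return PriorKnowledgeMatrix(
        row_ids=[f"r{i}" for i in range(values.shape[0])],
        group_names=[f"G{j}" for j in range(values.shape[1])],
        values=values,
    )


class TestLocalLogScore:
    def test_constant_column_no_parents(self):
        # three records all 0: 1! * 3! * 0! / 4! = 1/4
        data = _pkm([[0, 0], [0, 1], [0, 0]])
        assert local_log_score(0, [], data) == pytest.approx(math.log(1 / 4))

    def test_two_records_split_no_parents(self):
        # one 0 and one 1: 1! * 1! * 1! / 3! = 1/6
        data = _pkm([[0, 0], [1, 1]])
        assert local_log_score(0, [], data) == pytest.approx(math.log(1 / 6))

    def test_constant_parent_is_uninformative(self):
        # a constant parent leaves a single observed configuration, so the
        # score equals the parentless score
        data = _pkm([[0, 1, 0], [1, 1, 0], [1, 1, 1], [0, 1, 1]])
        assert local_log_score(0, [1], data) == pytest.approx(
            local_log_score(0, [], data)
        )

    def test_matches_factorial_oracle_on_random_small_data(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            rows = rng.integers(1, 7)
            cols = rng.integers(2, 4)
            values = rng.integers(0, 2, size=(rows, cols))
            data = _pkm(values)
            node = int(rng.integers(cols))
            others = [j for j in range(cols) if j != node]
            k = int(rng.integers(0, len(others) + 1))
            parents = list(rng.choice(others, size=k, replace=False))
            assert local_log_score(node, parents, data) == pytest.approx(
                pure_python_local_score(node, parents, values), rel=1e-12
            )

    def test_node_out_of_range(self, tiny_matrix):
        with pytest.raises(IndexError):
            local_log_score(7, [], tiny_matrix)

    def test_self_parent_rejected(self, tiny_matrix):
        with pytest.raises(ValueError):
            local_log_score(0, [0], tiny_matrix)


class TestK2Learn:
    def test_perfect_copy_column_gets_the_edge(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 2, size=40)
        data = _pkm(np.column_stack([a, a]))
        net = k2_learn(TopologicalOrder([0, 1]), data)
        assert net.adjacency[0, 1] == 1 and net.adjacency[1, 0] == 0

    def test_independent_columns_yield_empty_network(self):
        rng = np.random.default_rng(3)
        data = _pkm(rng.integers(0, 2, size=(2000, 4)))
        empty = 0
        for seed in range(5):
            order = generate_orders(4, seed % 4, 1, seed)[0]
            net = k2_learn(order, data)
            empty += net.adjacency.sum() == 0
        assert empty >= 4  # score gain for independent columns is negative

    def test_max_parents_cap_enforced(self):
        rng = np.random.default_rng(1)
        a = rng.integers(0, 2, size=200)
        b = rng.integers(0, 2, size=200)
        c = (a | b) & (rng.random(200) < 0.95)
        data = _pkm(np.column_stack([a, b, c]))
        net = k2_learn(TopologicalOrder([0, 1, 2]), data,
                       K2Config(max_parents=1))
        assert net.adjacency.sum(axis=0).max() <= 1

    def test_max_parents_zero_disallowed(self):
        with pytest.raises(ValueError):
            K2Config(max_parents=0)

    def test_order_mismatch_rejected(self, tiny_matrix):
        with pytest.raises(ValueError):
            k2_learn(TopologicalOrder([0, 1]), tiny_matrix)

    def test_non_permutation_rejected(self):
        with pytest.raises(ValueError):
            TopologicalOrder([0, 0, 1])

    def test_respects_order_and_acyclicity(self):
        import networkx as nx

        rng = np.random.default_rng(9)
        data = _pkm(rng.integers(0, 2, size=(120, 6)))
        for seed in range(6):
            order = generate_orders(6, seed, 2, seed)[1]
            net = k2_learn(order, data)
            G = nx.DiGraph(net.adjacency)
            assert nx.is_directed_acyclic_graph(G)
            pos = {n: i for i, n in enumerate(order.sequence)}
            for p, c in net.edges():
                assert pos[p] < pos[c]

    def test_greedy_never_beats_exhaustive_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            rows = int(rng.integers(8, 30))
            cols = int(rng.integers(3, 6))
            values = rng.integers(0, 2, size=(rows, cols))
            data = _pkm(values)
            order = generate_orders(cols, int(rng.integers(cols)), 1,
                                    int(rng.integers(1000)))[0]
            net = k2_learn(order, data, K2Config(max_parents=3))
            greedy_total = 0.0
            oracle_total = 0.0
            for pos, node in enumerate(order.sequence):
                parents = sorted(int(p) for p in np.nonzero(net.adjacency[:, node])[0])
                greedy_total += pure_python_local_score(node, parents, values)
                _, best = exhaustive_best_parents(
                    node, order.sequence[:pos], values, max_parents=3
                )
                oracle_total += best
            assert greedy_total <= oracle_total + 1e-9

    def test_greedy_matches_oracle_with_single_dominant_parent(self):
        # chain with near-deterministic conditionals: each node has exactly
        # one strong parent, so greedy and exhaustive search coincide
        rng = np.random.default_rng(23)
        n, m = 4, 400
        X = np.zeros((m, n), dtype=np.int8)
        X[:, 0] = rng.integers(0, 2, size=m)
        for j in range(1, n):
            flip = rng.random(m) < 0.02
            X[:, j] = np.where(flip, 1 - X[:, j - 1], X[:, j - 1])
        data = _pkm(X)
        order = TopologicalOrder([0, 1, 2, 3])
        net = k2_learn(order, data, K2Config(max_parents=3))
        for pos, node in enumerate(order.sequence):
            greedy = tuple(sorted(int(p) for p in np.nonzero(net.adjacency[:, node])[0]))
            oracle, _ = exhaustive_best_parents(
                node, order.sequence[:pos], X, max_parents=3
            )
            assert greedy == tuple(oracle)

    def test_determinism(self, tiny_matrix):
        order = TopologicalOrder([2, 0, 1])
        a = k2_learn(order, tiny_matrix)
        b = k2_learn(order, tiny_matrix)
        np.testing.assert_array_equal(a.adjacency, b.adjacency)


class TestGenerateOrders:
    def test_two_nodes_single_permutation(self):
        for order in generate_orders(2, 0, 5, seed=1):
            assert order.sequence == (0, 1)

    def test_start_node_pinned_and_permutation_valid(self):
        orders = generate_orders(8, 3, 20, seed=7)
        assert len(orders) == 20
        for o in orders:
            assert o.start_node == 3
            assert sorted(o.sequence) == list(range(8))

    def test_seed_reproducibility(self):
        a = generate_orders(10, 2, 10, seed=99)
        b = generate_orders(10, 2, 10, seed=99)
        assert [o.sequence for o in a] == [o.sequence for o in b]

    def test_count_validation(self):
        with pytest.raises(ValueError):
            generate_orders(5, 0, 0, seed=1)
        with pytest.raises(ValueError):
            generate_orders(5, 9, 1, seed=1)


class TestLearnEnsemble:
    def test_cardinality_contract(self):
        rng = np.random.default_rng(2)
        data = _pkm(rng.integers(0, 2, size=(10, 5)))
        nets = learn_ensemble(data, 3, K2Config(seed=0))
        assert len(nets) == 15
        starts = [n.order.start_node for n in nets]
        assert starts == [s for s in range(5) for _ in range(3)]

    def test_two_columns_one_topology(self):
        data = _pkm([[0, 1], [1, 0], [1, 1]])
        nets = learn_ensemble(data, 1)
        assert len(nets) == 2

    def test_determinism_across_runs(self):
        rng = np.random.default_rng(4)
        data = _pkm(rng.integers(0, 2, size=(30, 4)))
        a = learn_ensemble(data, 2, K2Config(seed=5))
        b = learn_ensemble(data, 2, K2Config(seed=5))
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.adjacency, y.adjacency)
            assert x.order.sequence == y.order.sequence

    def test_single_column_rejected(self):
        data = _pkm([[0], [1]])
        with pytest.raises(ValueError):
            learn_ensemble(data, 2)


class TestDirectedNetworkInvariants:
    def test_self_loop_rejected(self):
        adj = np.zeros((3, 3), dtype=np.int8)
        adj[1, 1] = 1
        with pytest.raises(ValueError):
            DirectedNetwork(adj, TopologicalOrder([0, 1, 2]))

    def test_order_violation_rejected(self):
        adj = np.zeros((3, 3), dtype=np.int8)
        adj[2, 0] = 1  # parent after child in the order
        with pytest.raises(ValueError):
            DirectedNetwork(adj, TopologicalOrder([0, 1, 2]))
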