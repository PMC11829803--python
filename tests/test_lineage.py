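import itertools

import numpy as np
import pytest

from ccitraj import ExpressionMatrix
from ccitraj.lineage import (
    _chu_liu,
    cell_entropy,
    max_arborescence,
    orient_partition_graph,
    stable_state_entropy,
)
from ccitraj.partition import PartitionGraph, Partitioning


def make(values, genes=None):
    return ExpressionMatrix(np.asarray(values, dtype=float), [], genes or [])


class TestCellEntropy:
    def test_single_active_group_is_zero(self):
        mat = make([[5.0, 5.0, 0.0]], genes=["a", "b", "c"])
        groups = {"a": "f1", "b": "f1", "c": "f2"}
        assert cell_entropy(mat, groups)[0] == pytest.approx(0.0)

    def test_uniform_groups_give_log_g(self):
        mat = make([[5.0, 5.0, 5.0, 5.0]], genes=list("abcd"))
        groups = {"a": "f1", "b": "f2", "c": "f3", "d": "f4"}
        assert cell_entropy(mat, groups)[0] == pytest.approx(np.log(4))

    def test_two_of_three_groups_active(self):
        mat = make([[5.0, 5.0, 0.0]], genes=["a", "b", "c"])
        groups = {"a": "f1", "b": "f2", "c": "f3"}
        assert cell_entropy(mat, groups)[0] == pytest.approx(np.log(2))

    def test_default_grouping_is_log_expressed_count(self):
        mat = make([[5.0, 5.0, 5.0, 0.2, 0.0]])
        assert cell_entropy(mat)[0] == pytest.approx(np.log(3))

    def test_zero_activation_warns_and_returns_zero(self):
        mat = make([[0.0, 0.0]])
        with pytest.warns(UserWarning):
            assert cell_entropy(mat)[0] == 0.0

    def test_invariant_to_gene_order_and_joint_scaling(self):
        rng = np.random.default_rng(0)
        values = rng.uniform(0, 5, size=(10, 12))
        mat = make(values)
        perm = rng.permutation(12)
        mat_perm = ExpressionMatrix(values[:, perm], mat.cell_ids, [mat.gene_ids[i] for i in perm])
        assert np.allclose(cell_entropy(mat), cell_entropy(mat_perm))
        mat_scaled = ExpressionMatrix(values * 3.0, mat.cell_ids, mat.gene_ids)
        assert np.allclose(cell_entropy(mat, threshold=1.0), cell_entropy(mat_scaled, threshold=3.0))


class TestStableStateEntropy:
    def test_quarter_core_takes_lowest(self):
        part = Partitioning(np.zeros(4, dtype=int), 1.0, 0.0)
        sse, cores = stable_state_entropy(np.array([4.0, 3.0, 2.0, 1.0]), part, 0.25)
        assert sse[0] == pytest.approx(1.0)
        assert list(cores[0]) == [3]

    def test_full_fraction_is_mean(self):
        part = Partitioning(np.zeros(4, dtype=int), 1.0, 0.0)
        sse, _ = stable_state_entropy(np.array([4.0, 3.0, 2.0, 1.0]), part, 1.0)
        assert sse[0] == pytest.approx(2.5)

    def test_singleton_partition(self):
        part = Partitioning(np.array([0, 1]), 1.0, 0.0)
        sse, _ = stable_state_entropy(np.array([2.0, 7.0]), part, 0.25)
        assert sse[1] == pytest.approx(7.0)

    def test_tie_broken_by_cell_index(self):
        part = Partitioning(np.zeros(4, dtype=int), 1.0, 0.0)
        _, cores = stable_state_entropy(np.array([1.0, 1.0, 1.0, 1.0]), part, 0.25)
        assert list(cores[0]) == [0]


class TestOrientation:
    def test_high_points_to_low(self):
        pg = PartitionGraph(np.array([[0.0, 0.7], [0.7, 0.0]]), np.array([3, 3]))
        edges = orient_partition_graph(pg, np.array([2.0, 1.0]))
        assert edges == [(0, 1, 0.7)]

    def test_tie_directed_from_lower_id(self):
        pg = PartitionGraph(np.array([[0.0, 0.7], [0.7, 0.0]]), np.array([3, 3]))
        edges = orient_partition_graph(pg, np.array([1.0, 1.0]))
        assert edges == [(0, 1, 0.7)]

    def test_empty_graph(self):
        pg = PartitionGraph(np.zeros((2, 2)), np.array([1, 1]))
        assert orient_partition_graph(pg, np.array([1.0, 2.0])) == []


def brute_force_max_arborescence(n, edges, root):
    """Exhaustive maximum over all spanning arborescences rooted at root."""
    in_edges = {v: [(u, v, w) for u, v2, w in edges if v2 == v and u != v] for v in range(n)}
    best = None
    non_root = [v for v in range(n) if v != root]
    for choice in itertools.product(*(in_edges[v] for v in non_root)):
        parent = {v: e[0] for v, e in zip(non_root, choice)}
        # acyclicity + reachability from root
        ok = True
        for v in non_root:
            seen = set()
            u = v
            while u != root:
                if u in seen or u not in parent:
                    ok = False
                    break
                seen.add(u)
                u = parent[u]
            if not ok:
                break
        if ok:
            w = sum(e[2] for e in choice)
            if best is None or w > best:
                best = w
    return best


class TestChuLiu:
    def test_star_forced_edges(self):
        edges = [(0, 1, 0.9), (0, 2, 0.8)]
        tree = max_arborescence(edges, sse=np.array([3.0, 2.0, 1.0]), n_partitions=3)
        assert sorted(tree.edges) == sorted(edges)
        assert tree.root_partitions == {0}

    @pytest.mark.parametrize("trial", range(20))
    def test_matches_exhaustive_enumeration(self, trial):
        rng = np.random.default_rng(100 + trial)
        n = int(rng.integers(4, 7))
        root = 0
        edges = []
        for u in range(n):
            for v in range(n):
                if u != v and v != root and rng.uniform() < 0.7:
                    edges.append((u, v, float(np.round(rng.uniform(0.1, 1.0), 3))))
        # ensure reachability: a directed path 0 -> 1 -> ... -> n-1
        for v in range(1, n):
            edges.append((v - 1, v, float(np.round(rng.uniform(0.1, 1.0), 3))))
        expected = brute_force_max_arborescence(n, edges, root)
        got = _chu_liu(list(range(n)), edges, root)
        assert len(got) == n - 1
        parents = [e[1] for e in got]
        assert sorted(parents) == list(range(1, n))  # in-degree one each
        assert sum(e[2] for e in got) == pytest.approx(expected)

    def test_matches_networkx_on_random_digraphs(self):
        nx = pytest.importorskip("networkx")
        from networkx.algorithms.tree.branchings import maximum_spanning_arborescence

        for trial in range(10):
            rng = np.random.default_rng(200 + trial)
            n = 6
            g = nx.DiGraph()
            g.add_nodes_from(range(n))
            edges = []
            for v in range(1, n):
                for u in range(n):
                    if u != v and rng.uniform() < 0.8:
                        w = float(np.round(rng.uniform(0.1, 1.0), 3))
                        edges.append((u, v, w))
                        g.add_edge(u, v, weight=w)
            try:
                ref = maximum_spanning_arborescence(g, attr="weight")
            except nx.NetworkXException:
                continue
            ref_root = next(v for v in ref.nodes if ref.in_degree(v) == 0)
            got = _chu_liu(list(range(n)), [e for e in edges if e[1] != ref_root], ref_root)
            assert sum(w for _, _, w in got) == pytest.approx(
                sum(d["weight"] for _, _, d in ref.edges(data=True))
            )

    def test_entropy_oriented_dag_equals_best_in_edge(self):
        """With strictly decreasing entropy no cycle can form, so the
        arborescence is the per-node argmax of incoming weight."""
        rng = np.random.default_rng(9)
        for _ in range(10):
            n = 7
            sse = np.sort(rng.uniform(0, 5, size=n))[::-1]  # node 0 highest
            theta = np.triu(rng.uniform(0.05, 1.0, size=(n, n)) * (rng.uniform(size=(n, n)) < 0.7), 1)
            theta = theta + theta.T
            # make sure every node has an inbound option from a lower index
            for v in range(1, n):
                if not theta[:v, v].any():
                    theta[v - 1, v] = theta[v, v - 1] = 0.5
            pg = PartitionGraph(theta, np.ones(n, dtype=int))
            directed = orient_partition_graph(pg, sse)
            tree = max_arborescence(directed, sse, n)
            for v in range(1, n):
                best_u = int(np.argmax(theta[:v, v]))
                assert (best_u, v, theta[best_u, v]) in tree.edges

    def test_orphan_node_becomes_own_root(self):
        # node 2 only has an outgoing edge into the main tree
        edges = [(0, 1, 0.5), (2, 1, 0.9)]
        sse = np.array([3.0, 1.0, 2.0])
        with pytest.warns(UserWarning, match="orphan"):
            tree = max_arborescence(edges, sse, 3)
        assert tree.root_partitions == {0, 2}
        assert (2, 1, 0.9) in tree.edges or (0, 1, 0.5) in tree.edges

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            max_arborescence([(0, 1, -0.1)], np.array([2.0, 1.0]), 2)
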