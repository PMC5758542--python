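import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from modgain.connectome import BinaryGraph, ConnectivityMatrix
from modgain.netmetrics import (ASSOCIATION_MODULES, Partition,
                                canonical_partition, modularity_q,
                                module_segregation, read_partition_table,
                                spectral_partition, subnetwork_modularity)

from conftest import edge_count_modularity, two_cliques_graph


def _random_graph(rng, n, p_edge):
    adj = (rng.random((n, n)) < p_edge).astype(int)
    adj = np.triu(adj, 1)
    adj = adj + adj.T
    return adj


def _partition(labels, g, source="canonical"):
    return Partition(labels=tuple(labels), roi_ids=g.roi_ids, source=source)


class TestModularityQ:
    def test_single_module_partition_is_zero(self, rng):
        adj = _random_graph(rng, 7, 0.5)
        g = BinaryGraph(adjacency=adj, cost=1.0)
        res = modularity_q(g, _partition([0] * 7, g))
        assert res.q == pytest.approx(0.0, abs=1e-12)
        assert res.e_within[0] == pytest.approx(1.0)
        assert res.a_totals[0] == pytest.approx(1.0)

    def test_two_triangles_half(self):
        g, labels = two_cliques_graph(3)
        res = modularity_q(g, _partition(labels, g))
        assert res.q == pytest.approx(0.5, abs=1e-15)
        assert res.e_within[0] == pytest.approx(0.5)
        assert res.a_totals[0] == pytest.approx(0.5)

    def test_matches_edge_counting_oracle(self, rng):
        """200 random graphs/partitions agree with brute-force edge counting."""
        for _ in range(200):
            n = rng.integers(3, 9)
            adj = _random_graph(rng, n, rng.uniform(0.3, 0.8))
            if adj.sum() == 0:
                continue
            g = BinaryGraph(adjacency=adj, cost=1.0)
            labels = rng.integers(0, 3, n)
            expected = edge_count_modularity(adj, labels)
            res = modularity_q(g, _partition(labels, g))
            assert res.q == pytest.approx(expected, abs=1e-12)

    def test_conservation_invariants(self, rng):
        adj = _random_graph(rng, 10, 0.4)
        g = BinaryGraph(adjacency=adj, cost=1.0)
        res = modularity_q(g, _partition(rng.integers(0, 4, 10), g))
        assert res.q == pytest.approx(sum(res.per_module_terms.values()), abs=1e-12)
        assert sum(res.a_totals.values()) == pytest.approx(1.0, abs=1e-12)
        assert sum(res.e_within.values()) <= 1.0 + 1e-12

    def test_edgeless_graph_raises(self):
        g = BinaryGraph(adjacency=np.zeros((3, 3), dtype=int), cost=1.0)
        with pytest.raises(ValueError, match="edgeless"):
            modularity_q(g, _partition([0, 0, 0], g))

    def test_invariant_under_relabeling(self, rng):
        adj = _random_graph(rng, 9, 0.5)
        g = BinaryGraph(adjacency=adj, cost=1.0)
        labels = rng.integers(0, 3, 9)
        q1 = modularity_q(g, _partition(labels, g)).q
        q2 = modularity_q(g, _partition([f"m{l}" for l in labels], g)).q
        assert q1 == pytest.approx(q2, abs=1e-15)


class TestSpectralPartition:
    def test_recovers_two_triangles(self):
        g, labels = two_cliques_graph(3)
        p = spectral_partition(g)
        assert p.q == pytest.approx(0.5, abs=1e-12)
        assert adjusted_rand_score(labels, p.labels) == 1.0

    def test_complete_graph_single_module(self):
        adj = 1 - np.eye(8, dtype=int)
        g = BinaryGraph(adjacency=adj, cost=1.0)
        p = spectral_partition(g)
        assert p.m == 1
        assert p.q == pytest.approx(0.0, abs=1e-12)

    def test_planted_four_blocks_recovered(self):
        """Planted-partition graphs (p_in=0.6, p_out=0.05) are recovered."""
        hits = 0
        labels = np.repeat(np.arange(4), 15)
        for seed in range(30):
            r = np.random.default_rng(5000 + seed)
            p_conn = np.where(labels[:, None] == labels[None, :], 0.6, 0.05)
            adj = (r.random((60, 60)) < p_conn).astype(int)
            adj = np.triu(adj, 1)
            adj = adj + adj.T
            g = BinaryGraph(adjacency=adj, cost=1.0)
            part = spectral_partition(g)
            hits += adjusted_rand_score(labels, part.labels) >= 0.9
        assert hits >= 29

    def test_disconnected_components_partitioned_independently(self):
        g, _ = two_cliques_graph(4)
        p = spectral_partition(g)
        groups = {frozenset(i for i, l in enumerate(p.labels) if l == lab)
                  for lab in set(p.labels)}
        assert groups == {frozenset(range(4)), frozenset(range(4, 8))}

    def test_deterministic(self, rng):
        adj = _random_graph(rng, 20, 0.3)
        g = BinaryGraph(adjacency=adj, cost=1.0)
        p1 = spectral_partition(g)
        p2 = spectral_partition(g)
        assert p1.labels == p2.labels and p1.q == p2.q

    def test_spectral_at_least_canonical(self, rng):
        """The maximizer is never beaten by an arbitrary fixed partition."""
        for _ in range(20):
            adj = _random_graph(rng, 15, 0.3)
            if adj.sum() == 0:
                continue
            g = BinaryGraph(adjacency=adj, cost=1.0)
            fixed = _partition(rng.integers(0, 4, 15), g)
            assert spectral_partition(g).q >= modularity_q(g, fixed).q - 1e-9


class TestCanonicalPartition:
    def test_thirteen_modules(self):
        ids = [f"roi{i:03d}" for i in range(252)]
        labels = [f"mod{i % 13}" for i in range(252)]
        p = canonical_partition(dict(zip(ids, labels)), ids)
        assert p.m == 13
        assert p.source == "canonical"

    def test_duplicate_roi_rejected(self):
        df = pd.DataFrame({"roi": ["a", "a", "b"], "module": ["x", "x", "y"]})
        with pytest.raises(ValueError, match="duplicate"):
            canonical_partition(df, ["a", "b"])

    def test_missing_roi_rejected(self):
        with pytest.raises(KeyError):
            canonical_partition({"a": "x"}, ["a", "b"])

    def test_row_order_irrelevant(self, tmp_path):
        ids = ["a", "b", "c"]
        fwd = tmp_path / "fwd.tsv"
        rev = tmp_path / "rev.tsv"
        fwd.write_text("a\tm1\nb\tm1\nc\tm2\n")
        rev.write_text("c\tm2\nb\tm1\na\tm1\n")
        assert (read_partition_table(fwd, ids).labels
                == read_partition_table(rev, ids).labels)


class TestSubnetworkModularity:
    def test_all_modules_equals_whole_brain(self, rng):
        adj = _random_graph(rng, 12, 0.4)
        g = BinaryGraph(adjacency=adj, cost=1.0)
        p = _partition(rng.integers(0, 3, 12), g)
        whole = modularity_q(g, p).q
        assert subnetwork_modularity(g, p, p.module_labels) == pytest.approx(
            whole, abs=1e-12)

    def test_empty_class_is_zero(self):
        g, labels = two_cliques_graph(3)
        assert subnetwork_modularity(g, _partition(labels, g), []) == 0.0

    def test_single_clique_contribution(self):
        g, labels = two_cliques_graph(3)
        val = subnetwork_modularity(g, _partition(labels, g), [0])
        assert val == pytest.approx(0.25, abs=1e-12)

    def test_unknown_label_raises(self):
        g, labels = two_cliques_graph(3)
        with pytest.raises(KeyError):
            subnetwork_modularity(g, _partition(labels, g), ["nope"])

    def test_subgraph_method_on_clique(self):
        g, labels = two_cliques_graph(3)
        val = subnetwork_modularity(g, _partition(labels, g), [0],
                                    method="subgraph")
        assert val == pytest.approx(0.0, abs=1e-12)  # one clique alone: Q=0


class TestModuleSegregation:
    @staticmethod
    def _zm(values, ids):
        return ConnectivityMatrix(values=values, scale="fisher_z", roi_ids=ids)

    def test_zero_between_gives_one(self):
        ids = tuple("abcdef")
        w = np.zeros((6, 6))
        w[:3, :3] = 0.8
        w[3:, 3:] = 0.6
        np.fill_diagonal(w, 0.0)
        p = Partition(labels=(0, 0, 0, 1, 1, 1), roi_ids=ids, source="canonical")
        res = module_segregation(self._zm(w, ids), p)
        assert res.segregation == pytest.approx(1.0, abs=1e-12)

    def test_homogeneous_matrix_gives_zero(self):
        ids = tuple("abcdef")
        w = np.full((6, 6), 0.5)
        np.fill_diagonal(w, 0.0)
        p = Partition(labels=(0, 0, 0, 1, 1, 1), roi_ids=ids, source="canonical")
        res = module_segregation(self._zm(w, ids), p)
        assert res.segregation == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_fixture(self):
        ids = tuple("abcdef")
        w = np.zeros((6, 6))
        vals = {(0, 1): 0.9, (0, 2): 0.7, (1, 2): 0.8,       # within module 0
                (3, 4): 0.6, (3, 5): 0.4, (4, 5): 0.5}       # within module 1
        between = {(0, 3): 0.1, (0, 4): 0.2, (0, 5): 0.0,
                   (1, 3): 0.3, (1, 4): 0.1, (1, 5): 0.2,
                   (2, 3): 0.0, (2, 4): 0.1, (2, 5): 0.1}
        for (i, j), v in {**vals, **between}.items():
            w[i, j] = w[j, i] = v
        p = Partition(labels=(0, 0, 0, 1, 1, 1), roi_ids=ids, source="canonical")
        res = module_segregation(self._zm(w, ids), p)
        zw = np.mean(list(vals.values()))
        zb = np.mean(list(between.values()))
        assert res.zw == pytest.approx(zw, abs=1e-12)
        assert res.zb == pytest.approx(zb, abs=1e-12)
        assert res.segregation == pytest.approx((zw - zb) / zw, abs=1e-12)

    def test_scope_restriction(self):
        ids = tuple(f"r{i}" for i in range(9))
        w = np.full((9, 9), 0.2)
        w[:3, :3] = 0.9
        np.fill_diagonal(w, 0.0)
        labels = ("a", "a", "a", "b", "b", "b", "c", "c", "c")
        p = Partition(labels=labels, roi_ids=ids, source="canonical")
        res = module_segregation(self._zm(w, ids), p, scope=["a"])
        assert res.zw == pytest.approx(0.9)
        assert res.zb == pytest.approx(0.2)

    def test_zero_zw_raises(self):
        ids = tuple("abcd")
        w = np.zeros((4, 4))
        w[0, 2] = w[2, 0] = 0.5
        p = Partition(labels=(0, 0, 1, 1), roi_ids=ids, source="canonical")
        with pytest.raises(ValueError, match="Zw"):
            module_segregation(self._zm(w, ids), p)
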