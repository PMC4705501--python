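"""Density-modularity scores, merge gains, CAD values and cache coherence."""

import math
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adm.density_modularity import (NO_MOVE, Partition, external_cad,
                                    internal_cad, merge_gain,
                                    partition_density, partition_phi)
from adm.graph_io import PPINetwork

from conftest import (TRIANGLES_EDGES, oracle_density, random_graph,
                      random_membership)


def make_partition(edges, blocks, nodes=()):
    net = PPINetwork.from_edges(edges, nodes=nodes)
    membership = {v: i for i, block in enumerate(blocks) for v in block}
    return Partition(net, membership)


class TestPartitionDensity:
    def test_isolated_singleton_contributes_zero(self):
        # one-edge graph plus isolated node c in its own module
        part = make_partition([("a", "b")], [["a", "b"], ["c"]], nodes=["c"])
        assert partition_density(part) == pytest.approx(-3.75, abs=1e-12)

    def test_two_disjoint_triangles(self):
        part = make_partition(TRIANGLES_EDGES, [["a", "b", "c"], ["x", "y", "z"]])
        assert partition_density(part) == pytest.approx(-1.0, abs=1e-12)

    def test_single_edge_pair_module(self):
        part = make_partition([("a", "b")], [["a", "b"]])
        assert partition_density(part) == pytest.approx(0.25 - 4.0, abs=1e-12)

    def test_edgeless_network_rejected(self):
        net = PPINetwork.from_edges([], nodes=["a", "b"])
        with pytest.raises(ValueError, match="L = 0"):
            partition_density(Partition.singletons(net))

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_raw_edge_list_oracle(self, seed):
        nodes, edges = random_graph(seed)
        memb = random_membership(seed + 1000, nodes)
        part = Partition(PPINetwork.from_edges(edges, nodes=nodes), memb)
        blocks = [list(s) for s in part.members.values()]
        assert partition_density(part) == pytest.approx(
            oracle_density(nodes, edges, blocks), abs=1e-12)


class TestMergeGain:
    def test_two_disconnected_singletons_zero(self):
        # c-d provides the required edge; a and b are disconnected singletons
        part = make_partition([("c", "d")], [["a"], ["b"], ["c", "d"]],
                              nodes=["a", "b"])
        assert merge_gain(part, 0, 1) == 0.0

    def test_bridged_triangles_minimum_reduction(self):
        part = make_partition(
            TRIANGLES_EDGES + [("c", "x")],
            [["a", "b", "c"], ["x", "y", "z"]])
        assert merge_gain(part, 0, 1) == pytest.approx(49 / 36 - 2, abs=1e-12)

    def test_triple_bridge_positive_gain(self):
        edges = TRIANGLES_EDGES + [("a", "x"), ("b", "y"), ("c", "z")]
        part = make_partition(edges, [["a", "b", "c"], ["x", "y", "z"]])
        assert merge_gain(part, 0, 1) == pytest.approx(81 / 36 - 2, abs=1e-12)

    def test_same_module_rejected(self, two_triangles):
        part = Partition.singletons(two_triangles)
        with pytest.raises(ValueError):
            merge_gain(part, 0, 0)

    def test_retired_module_rejected(self, two_triangles):
        part = Partition.singletons(two_triangles)
        part.merge(0, 1)
        with pytest.raises(KeyError):
            merge_gain(part, 1, 2)

    @pytest.mark.parametrize("seed", range(25))
    def test_full_mode_equals_density_difference(self, seed):
        nodes, edges = random_graph(seed)
        memb = random_membership(seed + 2000, nodes)
        part = Partition(PPINetwork.from_edges(edges, nodes=nodes), memb)
        ids = part.module_ids()
        if len(ids) < 2:
            return  # single-module draw: nothing to merge
        rng = random.Random(seed)
        a, b = rng.sample(ids, 2)
        before = partition_density(part)
        gain = merge_gain(part, a, b, mode="full")
        part.merge(a, b)
        assert gain == pytest.approx(partition_density(part) - before,
                                     abs=1e-12)


class TestInternalCad:
    def triangle_plus_node(self):
        edges = [("t1", "t2"), ("t2", "t3"), ("t1", "t3"),
                 ("v", "t1"), ("v", "t2")]
        return make_partition(edges, [["t1", "t2", "t3", "v"]])

    def test_consistent_form(self):
        part = self.triangle_plus_node()
        # v against the triangle: l2=3, n2=3, e_in=2
        assert internal_cad(part, "v").value == pytest.approx(
            25 / 16 - 1, abs=1e-12)

    def test_printed_form(self):
        part = self.triangle_plus_node()
        assert internal_cad(part, "v", form="eq5_as_printed").value == \
            pytest.approx(1.0, abs=1e-12)

    def test_no_edges_no_gain_under_both_forms(self):
        # host {a, c} has no internal edge (l2 = 0) and c has e_in = 0
        part = make_partition([("a", "b")], [["a", "c"], ["b"]],
                              nodes=["c"])
        for form in ("consistent", "eq5_as_printed"):
            assert internal_cad(part, "c", form=form).value == 0.0

    def test_singleton_node_scores_zero(self, two_triangles):
        part = Partition.singletons(two_triangles)
        assert internal_cad(part, "a").value == 0.0

    def test_unknown_node_rejected(self, two_triangles):
        with pytest.raises(KeyError):
            internal_cad(Partition.singletons(two_triangles), "nope")


class TestExternalCad:
    def test_best_candidate_and_target(self):
        edges = [("t1", "t2"), ("t2", "t3"), ("t1", "t3"),
                 ("v", "t1"), ("v", "t2"), ("v", "m")]
        part = make_partition(edges, [["t1", "t2", "t3"], ["m"], ["v"]])
        res = external_cad(part, "v")
        assert res.value == pytest.approx(25 / 16 - 1, abs=1e-12)
        assert part.members[res.target] == {"t1", "t2", "t3"}

    def test_all_neighbors_internal_gives_sentinel(self, two_triangles):
        part = make_partition(TRIANGLES_EDGES,
                              [["a", "b", "c"], ["x", "y", "z"]])
        res = external_cad(part, "a")
        assert res.value == NO_MOVE and res.target is None

    def test_tie_resolves_to_smallest_module_id(self):
        edges = [("v", "p"), ("v", "q")]
        part = make_partition(edges, [["v"], ["p"], ["q"]])
        res = external_cad(part, "v")
        assert res.target == min(
            m for m in part.module_ids() if part.members[m] != {"v"})


class TestCacheCoherence:
    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), data=st.data())
    def test_random_move_merge_sequences_keep_caches_exact(self, seed, data):
        """Incremental l/n/d/e stay equal to from-scratch recounts."""
        nodes, edges = random_graph(seed)
        net = PPINetwork.from_edges(edges, nodes=nodes)
        part = Partition.singletons(net)
        n_ops = data.draw(st.integers(1, 12))
        rng = random.Random(seed ^ 0xBEEF)
        for _ in range(n_ops):
            ids = part.module_ids()
            if len(ids) >= 2 and rng.random() < 0.3:
                part.merge(*rng.sample(ids, 2))
            else:
                node = rng.choice(sorted(part.membership))
                part.move(node, rng.choice(ids))
            part.check_consistency()
        assert sum(part.l.values()) + sum(part.e.values()) == net.L
        assert sum(part.n.values()) == net.n_nodes

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_cad_invariant_under_relabeling(self, seed):
        """Renaming nodes and module ids leaves R_in and R_out unchanged."""
        nodes, edges = random_graph(seed)
        memb = random_membership(seed + 1, nodes)
        part = Partition(PPINetwork.from_edges(edges, nodes=nodes), memb)

        rng = random.Random(seed + 2)
        perm = dict(zip(nodes, rng.sample(["w" + v for v in nodes],
                                          len(nodes))))
        shift = {m: m + 100 for m in set(memb.values())}
        edges2 = [(perm[u], perm[v]) for u, v in edges]
        memb2 = {perm[v]: shift[m] for v, m in memb.items()}
        part2 = Partition(
            PPINetwork.from_edges(edges2, nodes=[perm[v] for v in nodes]),
            memb2)

        for v in nodes:
            assert internal_cad(part, v).value == pytest.approx(
                internal_cad(part2, perm[v]).value, abs=1e-12)
            r1, r2 = external_cad(part, v), external_cad(part2, perm[v])
            if r1.target is None:
                assert r2.target is None
            else:
                assert r1.value == pytest.approx(r2.value, abs=1e-12)
                assert shift[r1.target] == r2.target


def test_move_accepted_by_cad_comparison_strictly_increases_phi():
    """R_in < R_out moves raise the surrogate objective, ensuring termination."""
    for seed in range(30):
        nodes, edges = random_graph(seed)
        net = PPINetwork.from_edges(edges, nodes=nodes)
        part = Partition.singletons(net)
        rng = random.Random(seed)
        for _ in range(40):
            node = rng.choice(sorted(part.membership))
            r_out = external_cad(part, node)
            if r_out.target is None:
                continue
            r_in = internal_cad(part, node)
            if r_in.value < r_out.value:
                before = partition_phi(part)
                part.move(node, r_out.target)
                assert partition_phi(part) > before
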